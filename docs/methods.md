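# Methods

This note documents the models and procedures `asarscan` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Transcribed-locus calling

TLs are built by interval merging on read intervals, never on per-base
coverage: stranded reads with gaps ≤ `merge_gap` (default 1,000 bp) form
contigs, contigs with gaps ≤ `bridge_gap` (default 7,000 bp, sized to span
non-uniquely-mappable full-length LINE elements) form candidate loci, and
candidates of ≥ `min_length` (default 50,000 bp) survive. Both merge
stages share one sweep-line implementation over sorted inputs; unsorted
input is an error rather than silently sorted, so the caller's
equivalence with a brute-force connected-components oracle over the
pairwise gap graph is exact.

The "intergenic" requirement is enforced strand-specifically by default:
a candidate is dropped only when it overlaps a protein-coding gene on its
own strand, because the merge itself is strand-specific and very long
intergenic noncoding RNAs are defined against same-strand gene structure.
`strand_mode="any"` gives the strict variant. Whether bridging should be
iterated to a fixpoint is moot for plain intervals (a single pass is
idempotent); `iterate_bridge=True` exists for pre-made contig inputs.

Two MAPQ conventions coexist upstream: TL calling removes reads with
MAPQ ≤ 20, allele-specific counting removes MAPQ < 30. Both are exposed
per stage (`mapq_min`) rather than reconciled.

L1 content is the fraction of the locus span covered by the union of
L1-family repeat intervals; loci above 0.18 carry a `high_l1` flag (known
ASARs exceed ~0.3).

## Allelic expression imbalance

For counts (h₁, h₂) of haplotype-informative reads, AEI =
max(h₁, h₂)/(h₁+h₂) × 100; ties favor neither haplotype and are never
callable. Observations with fewer than `min_informative` (default 20)
reads are silent/insufficient and excluded from testing.

The AEI call combines two outlier criteria, both estimating the null
distribution of bi-allelic expression:

1. **Parametric.** Exact two-sided binomial test (minimum-likelihood
   two-sidedness, not a normal approximation — counts near the 20-read
   floor are common) against p₀ = 0.5, thresholded at p ≤ `alpha_p`
   (default 0.001) and Benjamini–Hochberg q ≤ `alpha_q` (default 0.01).
   The BH family is all tested locus × clone observations of one run,
   with TLs and coding genes corrected as separate families (they are
   reported as separate tallies).
2. **Non-parametric.** OLS of AEI on log₁₀(informative reads) over all
   tested observations (TLs and coding genes pooled), flagging
   standardized residuals ≥ `k_sd` (default 2.5). The residual scale is
   estimated per log-depth decile (global fallback for deciles with
   < 20 null members) from the observations *not* flagged by the
   parametric criterion, using 1.4826 × MAD. Two facts force this null-
   subset, robust estimate rather than the naive all-observation SD:
   with a fraction f of strong-AEI observations contaminating the scale,
   the attainable standardized residual is bounded by √((1−f)/f), which
   falls below 2.5 once f exceeds ~14% — while real clone panels show
   AEI at ~20% of loci; and mono-allelic loci carry about half the
   informative reads of a bi-allelic locus at equal expression, so they
   concentrate in the low-depth deciles and can locally exceed even the
   50% breakdown of the median. `robust_scale=False` restores a plain SD
   of the null subset.

The two flags are combined by intersection (default; the conservative
reading of "outlying both the parametric and non-parametric estimation")
or union — the two readings both appear in the source material, so the
combinator is a config switch. When a run has fewer than
`min_regression_obs` (default 50) tested observations the regression is
meaningless; the non-parametric criterion is disabled with a warning and
the call falls back to the parametric flag alone. A consequence of the
transcriptome-wide regression: AEI should be fitted on the full expressed
set (all TLs and coding genes, autosomes plus X), not on a small
mono-dominated subset such as the X loci alone.

States per clone: silent/insufficient below the read floor, mono-hap1 or
mono-hap2 when called (by the favored haplotype), biallelic otherwise.
Across clones, a locus is **random (epigenetic) AEI** when mono-allelic
states of *opposite* homologs occur in ≥ 2 clones (`opposite-homologs`),
`single-allele-only` when AEI always favors the same homolog, `not-AEI`
otherwise. Known-imprinted-gene exclusion is left to the caller as an
optional filter on the input locus list.

## Allele-specific replication timing

Early/Late counts are enumerated per haplotype in non-overlapping 250-kb
windows. Quantile normalization (rank-mean, ties sharing the mean of
their rank range) is applied jointly across all Early and Late vectors of
all clone × haplotype profiles by default (`per-fraction` and `None`
available; the normalization family is not dictated by the data, so it is
a config choice). The timing value is log₂((E + c)/(L + c)) with
pseudocount c = 1; windows with fewer than 10 raw reads are masked. No
smoothing is applied by default; a centered moving average is available
(`smooth`), since published profiles often appear smoothed but the
procedure is rarely stated.

SD_alleles is the ddof=1 standard deviation of the timing value across
contributing profiles: all 2n profiles in the `combined` scope, one
haplotype's n profiles in the allele-restricted scopes. Windows with
fewer than two unmasked contributors are masked. The outlier threshold is
center + k × SD of the genome-wide SD_alleles distribution over
*autosomal* windows only (the X is the internal control, not part of the
null), with k = 2.5 and center = mean by default (`median` available —
both centers appear in the source material; mean matches the printed
per-haplotype thresholds). A degenerate null (identical profiles, spread
≈ 0) yields no outliers rather than flagging float jitter. Consecutive
outlier windows (gaps of up to `max_join` − 1 interior windows absorbed;
default adjacent-only) merge into VERT loci; loci from different scopes
are unioned, keeping scope labels, for the combined tally.

## ASRT and polarity coordination

Within one clone, d = RT_hap1 − RT_hap2 per window; the default
asynchrony rule interprets "SD > 1" as the two-allele standard deviation,
SD({a,b}) = |d|/√2, i.e. |d| > √2 log₂ units. The z-score alternative
(`z_gt_1`) flags |d| above mean(|d|) + 1 SD(|d|) genome-wide. Consecutive
asynchronous windows merge into ASRT regions with polarity = sign of the
mean d (hap1-early / hap2-early).

Regions are matched across clones at ≥ 50% reciprocal overlap (matching
is against the first-seen member of a cluster; region boundaries from a
shared window grid make this stable) into a consensus region × clone
polarity matrix. The coordination statistic is the mean over clones of
the majority-orientation fraction among that clone's informative regions:
1 under perfect within-clone coordination (a clone-set where one clone is
all hap1-early and another all hap2-early still scores 1 — mirroring is
within-clone), ≈ 0.5 under independence with many regions. The null
flips each region × clone polarity independently with probability ½;
p = (1 + #{perm ≥ observed})/(1 + n_perm) with n_perm = 9,999 by default.
The statistic and its null are this package's formalization of a
comparison the source analysis made qualitatively; regions are weighted
equally (not by size), which is the simplest defensible choice. The test
is invariant under global haplotype relabeling, and permutation p-values
are valid (conservative on the discrete statistic grid).

## Synthetic data generator

The generator emulates the study design the pipeline targets: six
single-cell-derived clones of one individual, phased heterozygous SNPs at
density 1/1,500 bp, strand-specific informative RNA reads (100 bp, fully
contained in their locus, each covering a phased SNP with the correct
allele base), non-informative coverage reads for contiguity (10 per kb
per expressed allele), and binned Early/Late Repli-seq counts per
haplotype (500 reads per haplotype per 250-kb window).

Count law: totals are negative-binomial with var = μ + φμ² (RNA totals
φ = 0.05; Repli-seq counts φ = 0.01, near-Poisson as appropriate for
~10× WGS window counts; φ → 0 recovers Poisson exactly). Allelic splits
are binomial given the total, optionally beta-binomial with intra-class
correlation ρ = 0.001 modelling residual allele-level noise such as
mapping bias. The split construction matters: drawing the two alleles as
independent NB variables would inflate allelic-proportion variance to
~2.4× binomial at depth 200 and invalidate the binomial null of the AEI
test on *any* dataset — real allelic proportions are near-binomial given
the total, with overdispersion living in the shared expression level.
Silent alleles emit background at 1% of baseline depth so silent vs
insufficient classification is exercised (the true background level in
nuclear RNA-seq is not well characterized; 1% is a stand-in, exposed in
config).

Replication timing: each chromosome carries a smooth shared baseline
profile (sinusoid, amplitude 1.2, period 10 Mb — typical replication-
domain scale); planted RT loci override it with ±Δ per clone per
haplotype (Δ = 1.5 log₂ units). The X-like control chromosome has
alternating early/late segments; over early segments the "active"
haplotype 1 is early (+Δ) and haplotype 2 late (−Δ), elsewhere both are
late — reproducing the bimodal combined-SD distribution and the
single-polarity ASRT pattern of skewed X inactivation. X expression loci
are mono-hap1 except a seeded 20% of escape-like biallelic loci.

Counts-level generators (`simulate_aei_table`) serve the large
statistical suites directly, planting mono-allelic loci among a
bi-allelic background (500 among 4,500 in the recovery suite, ~10% — the
non-parametric criterion is calibrated against the whole expressed set,
so the background is part of the study condition). Per-locus expression
is lognormal around depth 100 (floored at 50 in the recovery setting); a
configurable fraction of mono loci draw each clone's homolog
independently (random epigenetic AEI), the rest keep one homolog
throughout.

One RNG stream is seeded per dataset with per-clone sub-streams spawned
deterministically; identical seeds give byte-identical outputs.

**What the generator does not emulate.** Sequencing errors, splicing,
fragment-length structure, mappability variation, reference bias,
GC-dependent coverage, aneuploidy, and any genetic (eQTL/rtQTL) source of
allelic asymmetry — planted states are purely epigenetic by construction.
Planted AEI is binary (fully mono or fully balanced), whereas real AEI is
a continuum; recovery rates measured here therefore speak to the
machinery's correctness under the stated noise model, not to sensitivity
on real sequencing data. The read-level simulator also plants loci
sparsely, so TL-calling specificity against a transcriptionally noisy
genome is not measured.

## Problem sizes and numerical choices

The shipped suites run at desk scale by design: genomes of a few hundred
250-kb windows, thousands of simulated loci, and read counts in the
10²–10³ range per locus — large enough for the binomial/BH/regression and
SD-threshold machinery to operate in its asymptotic regime, small enough
to run in seconds. Degenerate inputs are handled explicitly: zero-total
observations are undefined (never 0/0), all-identical profiles produce no
SD outliers, constant samples cannot be quantile-normalized (error), a
single contributing profile masks the SD, and fewer than two informative
regions make the coordination test inconclusive rather than erroneous.
Tie-breaking is deterministic throughout (stable sorts, first-seen
cluster representatives, `.2`/`.3` ID suffixes).

## Known limitations

- BAM support covers the common single/paired-end short-read layouts;
  supplementary/secondary alignments are skipped, CRAM is out of scope.
- The TSV read dialect carries pre-assigned haplotype calls; when reading
  BAM, haplotype assignment needs the phased VCF supplied alongside.
- Coding-gene AEI uses the same read-counting machinery as TLs (span
  overlap), not exon-aware counting; for the desk-scale datasets this is
  exact by construction, for real GTFs it overcounts intronic signal.
- The coordination statistic treats regions as exchangeable units; if
  region sizes vary wildly a size-weighted variant would be needed.
- rtQTL intersection is a plain interval overlap helper
  (`report.overlap_with_bed`); no genetics is re-derived.
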