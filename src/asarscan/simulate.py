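"""Seeded generator of multi-clone phased datasets with known ground truth.

The generator emulates the study design the pipeline targets: several
single-cell-derived clones from one individual with a fully phased genome,
nuclear strand-specific RNA-seq per clone, and Early/Late Repli-seq per
clone per haplotype.  Planted transcribed loci and coding genes carry
programmable per-clone allelic expression states (``mono-hap1``,
``mono-hap2``, ``biallelic``, ``silent``); planted replication-timing loci
carry programmable per-clone per-haplotype Early/Late states; one
chromosome can play an X-inactivation-like fully skewed internal control.

Counts follow a negative-binomial law parameterized by mean and dispersion
(dispersion -> 0 recovers Poisson).  Silent alleles emit background reads
at a configurable fraction of baseline (default 1%) so that "silent" vs
"insufficient reads" classification is exercised.  One RNG stream is
seeded from the config; per-clone sub-streams are derived
deterministically, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from asarscan.io import (
    HAP1,
    HAP2,
    UNINFORMATIVE,
    PhasedVariant,
    ReadRecord,
    write_tsv,
    _HAP_TSV,
)
from asarscan.layout import GenomeLayout

MONO_HAP1 = "mono-hap1"
MONO_HAP2 = "mono-hap2"
BIALLELIC = "biallelic"
SILENT = "silent"
EXPRESSION_STATES = (MONO_HAP1, MONO_HAP2, BIALLELIC, SILENT)

EARLY = "early"
LATE = "late"

_BASES = np.array(["A", "C", "G", "T"])

_SWAP_STATE = {MONO_HAP1: MONO_HAP2, MONO_HAP2: MONO_HAP1}


@dataclass(frozen=True)
class PlantedLocus:
    """A planted transcribed locus or coding gene with per-clone states."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    states: str | Mapping[str, str] = BIALLELIC

    def state_for(self, clone: str) -> str:
        if isinstance(self.states, str):
            return self.states
        return self.states.get(clone, SILENT)


@dataclass(frozen=True)
class PlantedRTLocus:
    """A planted replication-timing locus: per-clone (hap1, hap2) states."""

    chrom: str
    start: int
    end: int
    timing: tuple[str, str] | Mapping[str, tuple[str, str]] = (EARLY, EARLY)

    def timing_for(self, clone: str) -> tuple[str, str]:
        if isinstance(self.timing, Mapping):
            return tuple(self.timing.get(clone, (EARLY, EARLY)))
        return tuple(self.timing)


def default_layout() -> GenomeLayout:
    """Desk-scale layout: four 30-Mb autosomes plus a 15-Mb X-like control."""
    return GenomeLayout(
        {"chr1": 30_000_000, "chr2": 30_000_000, "chr3": 30_000_000,
         "chr4": 30_000_000, "chrX": 15_000_000},
        x_chromosome="chrX",
    )


@dataclass
class SimulationConfig:
    """Study-condition knobs for one simulated clone set.

    Defaults follow the targeted study design: six isogenic clones, a
    heterozygous SNP roughly every 1.5 kb, ~100 informative reads per
    expressed allele per locus, 250-kb Repli-seq windows with an
    Early/Late separation of |log2(E/L)| = 1.5 between an early and a
    late allele, and mild overdispersion.
    """

    seed: int = 0
    layout: GenomeLayout = field(default_factory=default_layout)
    n_clones: int = 6
    snp_density: float = 1.0 / 1500.0
    tls: Sequence[PlantedLocus] = ()
    genes: Sequence[PlantedLocus] = ()
    rt_loci: Sequence[PlantedRTLocus] = ()
    depth: float = 100.0                 # informative reads per expressed allele
    repliseq_reads_per_window: float = 500.0   # per haplotype per 250-kb window
    dispersion: float = 0.05             # RNA-seq totals
    allelic_overdispersion: float = 0.001  # beta-binomial rho of the allelic split
    repliseq_dispersion: float = 0.01    # WGS-derived E/L counts, near-Poisson
    background_fraction: float = 0.01    # silent-allele background, fraction of depth
    delta: float = 1.5                   # |log2(E/L)| of an early/late allele
    window: int = 250_000
    read_length: int = 100
    coverage_reads_per_kb: float = 10.0  # non-informative reads per expressed allele
    emit_coverage_reads: bool = True
    baseline_amplitude: float = 1.2      # autosomal synchronous RT profile
    baseline_period: float = 10e6
    x_control: bool = False
    x_escape_fraction: float = 0.2
    x_early_blocks: int = 8              # alternating early/late segments on the X

    @property
    def clones(self) -> list[str]:
        return [f"clone{i + 1}" for i in range(self.n_clones)]

    def validate(self) -> None:
        for locus in list(self.tls) + list(self.genes):
            if locus.chrom not in self.layout:
                raise ValueError(f"planted locus on unknown chromosome {locus.chrom}")
            if locus.start < 0 or locus.end > self.layout.length(locus.chrom):
                raise ValueError(
                    f"planted locus {locus.chrom}:{locus.start}-{locus.end} "
                    "outside chromosome bounds"
                )
        for locus in self.rt_loci:
            if locus.chrom not in self.layout:
                raise ValueError(f"planted RT locus on unknown chromosome {locus.chrom}")
            if locus.start < 0 or locus.end > self.layout.length(locus.chrom):
                raise ValueError(
                    f"planted RT locus {locus.chrom}:{locus.start}-{locus.end} "
                    "outside chromosome bounds"
                )
        _check_non_overlapping(self.tls)
        _check_non_overlapping(self.genes)


def _check_non_overlapping(loci: Sequence[PlantedLocus]) -> None:
    by_key: dict[tuple[str, str], list[PlantedLocus]] = {}
    for locus in loci:
        by_key.setdefault((locus.chrom, locus.strand), []).append(locus)
    for group in by_key.values():
        group = sorted(group, key=lambda x: x.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"planted loci overlap on the same strand: "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    expression: pd.DataFrame          # index locus id, columns clones, state strings
    locus_info: pd.DataFrame          # locus, chrom, start, end, strand, kind
    random_aei: pd.Series             # bool per locus (>=2 clones, opposite homologs)
    rt_loci: pd.DataFrame             # locus, chrom, start, end
    rt_timing: pd.DataFrame           # locus, clone, hap1, hap2 (early/late)
    vert: pd.Series                   # bool per RT locus
    rt_windows: pd.DataFrame          # chrom, start, end, clone, haplotype, mean_log2


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    variants: list[PhasedVariant]
    reads: dict[str, list[ReadRecord]]
    repliseq: pd.DataFrame            # chrom, start, end, clone, haplotype, early, late
    truth: GroundTruth


# ---------------------------------------------------------------------------
# count law

def nb_counts(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial counts with var = mean + dispersion * mean^2.

    ``dispersion <= 0`` falls back to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, np.where(mean > 0, p, 1.0))


def allelic_counts(
    rng: np.random.Generator,
    mean1: float,
    mean2: float,
    dispersion: float,
    allelic_rho: float = 0.001,
) -> tuple[int, int]:
    """Draw (hap1, hap2) counts: overdispersed total, near-binomial split.

    Expression-level noise (negative binomial, ``dispersion``) acts on the
    shared total; the allelic proportion given the total is binomial, or
    beta-binomial with intra-class correlation ``allelic_rho`` modelling
    residual allele-level noise (mapping bias and the like).  Drawing the
    two alleles as independent NB variables instead would inflate the
    proportion variance far beyond anything seen in allelic RNA-seq and
    void the binomial null of downstream AEI testing.
    """
    total_mean = mean1 + mean2
    if total_mean <= 0:
        return 0, 0
    total = int(nb_counts(rng, total_mean, dispersion))
    if total == 0:
        return 0, 0
    p = mean1 / total_mean
    if allelic_rho > 0 and 0 < p < 1:
        s = (1.0 - allelic_rho) / allelic_rho
        p = rng.beta(p * s, (1.0 - p) * s)
    h1 = int(rng.binomial(total, p))
    return h1, total - h1


# ---------------------------------------------------------------------------
# ground-truth bookkeeping

def recompute_random_aei(expression: pd.DataFrame) -> pd.Series:
    """Random-AEI flag: opposite mono-allelic states in >=2 clones."""
    has1 = (expression == MONO_HAP1).any(axis=1)
    has2 = (expression == MONO_HAP2).any(axis=1)
    return has1 & has2


def _locus_id(kind: str, i: int, locus: PlantedLocus) -> str:
    chrom_token = locus.chrom.removeprefix("chr")
    mb = locus.start / 1e6
    label = f"{chrom_token}-{mb:g}"
    prefix = "TL" if kind == "TL" else "G"
    return f"{prefix}:{label}"


# ---------------------------------------------------------------------------
# main generator

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate phased variants, per-clone RNA reads, and Repli-seq counts."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_variants, ss_rna, ss_repli, ss_misc = root.spawn(4)
    rng_variants = np.random.default_rng(ss_variants)

    variants = _simulate_variants(config, rng_variants)
    pos_by_chrom = {
        chrom: np.array([v.pos for v in variants if v.chrom == chrom])
        for chrom in config.layout
    }

    clones = config.clones
    rna_streams = {c: np.random.default_rng(s) for c, s in zip(clones, ss_rna.spawn(len(clones)))}

    loci = [("TL", locus) for locus in config.tls] + [("coding", locus) for locus in config.genes]
    locus_rows = []
    state_rows: dict[str, dict[str, str]] = {}
    reads: dict[str, list[ReadRecord]] = {c: [] for c in clones}

    seen_ids: dict[str, int] = {}
    for i, (kind, locus) in enumerate(loci):
        lid = _locus_id(kind, i, locus)
        if lid in seen_ids:
            seen_ids[lid] += 1
            lid = f"{lid}.{seen_ids[lid]}"
        else:
            seen_ids[lid] = 1
        locus_rows.append(
            dict(locus=lid, chrom=locus.chrom, start=locus.start, end=locus.end,
                 strand=locus.strand, kind=kind)
        )
        state_rows[lid] = {c: locus.state_for(c) for c in clones}
        for clone in clones:
            _simulate_locus_reads(
                config, rna_streams[clone], locus, state_rows[lid][clone],
                pos_by_chrom[locus.chrom], reads[clone],
            )

    for clone in clones:
        reads[clone].sort(key=lambda r: (r.chrom, r.start, r.end))

    repliseq, rt_windows = _simulate_repliseq(config, ss_repli)

    locus_info = pd.DataFrame(
        locus_rows, columns=["locus", "chrom", "start", "end", "strand", "kind"]
    )
    expression = pd.DataFrame.from_dict(state_rows, orient="index", columns=clones)
    expression.index.name = "locus"
    if expression.empty:
        expression = pd.DataFrame(columns=clones, index=pd.Index([], name="locus"))

    rt_rows = []
    rt_locus_rows = []
    for j, rtl in enumerate(config.rt_loci):
        rid = f"RT:{rtl.chrom.removeprefix('chr')}-{rtl.start / 1e6:g}"
        rt_locus_rows.append(dict(locus=rid, chrom=rtl.chrom, start=rtl.start, end=rtl.end))
        for clone in clones:
            h1, h2 = rtl.timing_for(clone)
            rt_rows.append(dict(locus=rid, clone=clone, hap1=h1, hap2=h2))
    rt_timing = pd.DataFrame(rt_rows, columns=["locus", "clone", "hap1", "hap2"])
    rt_loci = pd.DataFrame(rt_locus_rows, columns=["locus", "chrom", "start", "end"])
    if len(rt_timing):
        vert = rt_timing.groupby("locus").apply(
            lambda g: g[["hap1", "hap2"]].to_numpy().ravel(), include_groups=False
        ).map(lambda states: len(set(states)) > 1)
        vert = vert.reindex(rt_loci["locus"])
    else:
        vert = pd.Series(dtype=bool, index=pd.Index([], name="locus"))

    truth = GroundTruth(
        expression=expression,
        locus_info=locus_info,
        random_aei=recompute_random_aei(expression),
        rt_loci=rt_loci,
        rt_timing=rt_timing,
        vert=vert,
        rt_windows=rt_windows,
    )
    return SimulatedDataset(config, variants, reads, repliseq, truth)


def _simulate_variants(config: SimulationConfig, rng: np.random.Generator) -> list[PhasedVariant]:
    variants: list[PhasedVariant] = []
    for chrom in config.layout:
        length = config.layout.length(chrom)
        n = rng.poisson(length * config.snp_density)
        positions = np.unique(rng.integers(0, length, size=n))
        ref_idx = rng.integers(0, 4, size=positions.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=positions.size)) % 4
        for pos, r, a in zip(positions, ref_idx, alt_idx):
            variants.append(PhasedVariant(chrom, int(pos), str(_BASES[r]), str(_BASES[a])))
    return variants


def _allele_means(config: SimulationConfig, state: str) -> tuple[float, float]:
    bg = config.depth * config.background_fraction
    if state == MONO_HAP1:
        return config.depth, bg
    if state == MONO_HAP2:
        return bg, config.depth
    if state == BIALLELIC:
        return config.depth, config.depth
    return bg, bg


def _simulate_locus_reads(
    config: SimulationConfig,
    rng: np.random.Generator,
    locus: PlantedLocus,
    state: str,
    snp_positions: np.ndarray,
    out: list[ReadRecord],
) -> None:
    length = locus.end - locus.start
    rl = min(config.read_length, length)
    in_locus = snp_positions[(snp_positions >= locus.start) & (snp_positions < locus.end)]
    mean1, mean2 = _allele_means(config, state)
    n1, n2 = allelic_counts(
        rng, mean1, mean2, config.dispersion, config.allelic_overdispersion
    )

    for hap, n in ((HAP1, n1), (HAP2, n2)):
        if n == 0 or in_locus.size == 0:
            continue
        snps = rng.choice(in_locus, size=n)
        lo = np.maximum(locus.start, snps - rl + 1)
        hi = np.minimum(snps, locus.end - rl)
        hi = np.maximum(hi, lo)
        starts = rng.integers(lo, hi + 1)
        for s in starts:
            out.append(ReadRecord(locus.chrom, int(s), int(s) + rl, locus.strand, 60, False, hap))

    if config.emit_coverage_reads and config.coverage_reads_per_kb > 0:
        weight = (mean1 + mean2) / max(config.depth, 1e-12)
        n_cov = rng.poisson(config.coverage_reads_per_kb * length / 1000.0 * weight)
        if n_cov:
            starts = rng.integers(locus.start, max(locus.end - rl, locus.start) + 1, size=n_cov)
            for s in starts:
                out.append(
                    ReadRecord(locus.chrom, int(s), int(s) + rl, locus.strand, 60, False, UNINFORMATIVE)
                )


# ---------------------------------------------------------------------------
# Repli-seq

def _delta_for(state: str, delta: float) -> float:
    return delta if state == EARLY else -delta


def x_early_block_mask(n_windows: int, n_blocks: int) -> np.ndarray:
    """Alternating early/late segmentation of the X-like chromosome.

    Splits the window grid into ``2 * n_blocks`` roughly equal segments and
    marks every other segment (starting with the first) as early.  The
    block count is clamped so every segment spans at least one window.
    """
    if n_windows <= 0:
        return np.zeros(0, dtype=bool)
    n_blocks = max(1, min(n_blocks, n_windows // 2 or 1))
    edges = np.linspace(0, n_windows, 2 * n_blocks + 1).astype(int)
    mask = np.zeros(n_windows, dtype=bool)
    for k in range(0, 2 * n_blocks, 2):
        mask[edges[k]:edges[k + 1]] = True
    return mask


def _simulate_repliseq(
    config: SimulationConfig, ss_repli: np.random.SeedSequence
) -> tuple[pd.DataFrame, pd.DataFrame]:
    clones = config.clones
    streams = {c: np.random.default_rng(s) for c, s in zip(clones, ss_repli.spawn(len(clones)))}
    phase_rng = np.random.default_rng(ss_repli.spawn(1)[0])

    rows = []
    mean_rows = []
    for chrom in config.layout:
        length = config.layout.length(chrom)
        n_win = length // config.window
        starts = np.arange(n_win) * config.window
        ends = starts + config.window
        centers = (starts + ends) / 2.0
        phase = phase_rng.uniform(0, 2 * np.pi)
        baseline = config.baseline_amplitude * np.sin(
            2 * np.pi * centers / config.baseline_period + phase
        )
        is_x = config.x_control and chrom == config.layout.x_chromosome
        if is_x:
            early_mask = x_early_block_mask(n_win, config.x_early_blocks)

        for clone in clones:
            rng = streams[clone]
            for hap in (HAP1, HAP2):
                mean_log2 = baseline.copy()
                if is_x:
                    # active X (hap1) early in the early segment; both
                    # haplotypes late elsewhere
                    mean_log2 = np.full(n_win, -config.delta)
                    if hap == HAP1:
                        mean_log2[early_mask] = config.delta
                for rtl in config.rt_loci:
                    if rtl.chrom != chrom:
                        continue
                    h1, h2 = rtl.timing_for(clone)
                    state = h1 if hap == HAP1 else h2
                    sel = (starts < rtl.end) & (ends > rtl.start)
                    mean_log2[sel] = _delta_for(state, config.delta)

                frac_early = 2.0 ** mean_log2 / (1.0 + 2.0 ** mean_log2)
                total = config.repliseq_reads_per_window
                early = nb_counts(rng, total * frac_early, config.repliseq_dispersion)
                late = nb_counts(rng, total * (1.0 - frac_early), config.repliseq_dispersion)
                for w in range(n_win):
                    rows.append(
                        (chrom, int(starts[w]), int(ends[w]), clone, hap,
                         int(early[w]), int(late[w]))
                    )
                    mean_rows.append(
                        (chrom, int(starts[w]), int(ends[w]), clone, hap,
                         float(mean_log2[w]))
                    )
    repliseq = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "clone", "haplotype", "early", "late"]
    )
    rt_windows = pd.DataFrame(
        mean_rows, columns=["chrom", "start", "end", "clone", "haplotype", "mean_log2"]
    )
    return repliseq, rt_windows


# ---------------------------------------------------------------------------
# X control

def x_escape_mask(seed: int, n_loci: int, fraction: float) -> np.ndarray:
    """Seeded Bernoulli mask selecting X-inactivation escape loci."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE5CA]))
    return rng.random(n_loci) < fraction


def simulate_x_control(
    config: SimulationConfig,
    n_loci: int = 20,
    locus_length: int = 60_000,
) -> SimulatedDataset:
    """Simulate the X-like fully skewed internal control chromosome.

    Every non-escape locus is mono-hap1 in every clone (the active X is
    haplotype 1); hap1 is early and hap2 late over the early segment of the
    chromosome.  A seeded minority of escape loci (``x_escape_fraction``)
    are biallelic.  Expression loci are spread along the chromosome.
    """
    x = config.layout.x_chromosome
    if x is None:
        raise ValueError("layout has no X-control chromosome designated")
    length = config.layout.length(x)
    escape = x_escape_mask(config.seed, n_loci, config.x_escape_fraction)
    slots = np.linspace(0, length - locus_length, n_loci).astype(int)
    tls = [
        PlantedLocus(x, int(s), int(s) + locus_length, "+",
                     BIALLELIC if escape[i] else MONO_HAP1)
        for i, s in enumerate(slots)
    ]
    sub = replace(
        config,
        layout=GenomeLayout({x: length}, x_chromosome=x),
        tls=tls,
        genes=(),
        rt_loci=(),
        x_control=True,
    )
    return simulate_dataset(sub)


# ---------------------------------------------------------------------------
# counts-level generator for the large statistical suites

def simulate_aei_table(
    seed: int,
    n_null: int = 4500,
    n_mono: int = 500,
    n_clones: int = 6,
    depth: float = 100.0,
    depth_sigma: float = 0.5,
    min_depth: float = 50.0,
    dispersion: float = 0.05,
    allelic_overdispersion: float = 0.001,
    background_fraction: float = 0.01,
    opposite_fraction: float = 0.3,
    kind: str = "TL",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a locus x clone allelic-count table with known states.

    Planted mono-allelic loci sit among a bi-allelic background, mimicking
    a transcriptome where strong AEI is the minority: the non-parametric
    AEI criterion estimates the residual spread of allelic bias from the
    whole expressed set, so the background is part of the study condition.
    Per-locus expression level is lognormal around ``depth`` (floored at
    ``min_depth``).  A fraction ``opposite_fraction`` of mono-allelic loci
    draw each clone's expressed homolog independently (random epigenetic
    AEI); the rest keep one homolog in every clone.

    Returns ``(observations, truth)``: observations has columns
    ``locus, clone, kind, hap1, hap2``; truth has per-observation state and
    a per-locus ``random_aei`` flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAE1]))
    clones = [f"clone{i + 1}" for i in range(n_clones)]
    rows = []
    truth_rows = []
    n_total = n_null + n_mono
    level = np.maximum(depth * rng.lognormal(0.0, depth_sigma, size=n_total), min_depth)
    for i in range(n_total):
        lid = f"L{i + 1}"
        is_mono = i >= n_null
        if is_mono:
            if rng.random() < opposite_fraction:
                haps = rng.integers(0, 2, size=n_clones)  # random epigenetic AEI
            else:
                haps = np.full(n_clones, rng.integers(0, 2))
        for j, clone in enumerate(clones):
            if is_mono:
                state = MONO_HAP1 if haps[j] == 0 else MONO_HAP2
            else:
                state = BIALLELIC
            bg = background_fraction * level[i]
            m1 = level[i] if state in (MONO_HAP1, BIALLELIC) else bg
            m2 = level[i] if state in (MONO_HAP2, BIALLELIC) else bg
            h1, h2 = allelic_counts(rng, m1, m2, dispersion, allelic_overdispersion)
            rows.append((lid, clone, kind, h1, h2))
            truth_rows.append((lid, clone, state))
    obs = pd.DataFrame(rows, columns=["locus", "clone", "kind", "hap1", "hap2"])
    truth = pd.DataFrame(truth_rows, columns=["locus", "clone", "state"])
    states_wide = truth.pivot(index="locus", columns="clone", values="state")
    flags = recompute_random_aei(states_wide).rename("random_aei")
    truth = truth.merge(flags.reset_index(), on="locus", how="left")
    return obs, truth


def vert_recovery_config(
    seed: int,
    n_loci: int = 20,
    n_clones: int = 6,
    locus_windows: int = 2,
) -> SimulationConfig:
    """Planted variable-timing loci among synchronous autosomal windows.

    Four 35-Mb autosomes give 560 windows at 250 kb; ``n_loci`` loci of
    ``locus_windows`` windows each carry one of three variability
    patterns, all with at least two clones deviating (a single-clone
    deviation is below the SD_alleles resolution of a six-clone set):

    * hap1 varies across clones (hap2 uniformly late),
    * hap2 varies across clones (hap1 uniformly late),
    * asynchrony with alternating polarity across clones.
    """
    layout = GenomeLayout({f"chr{i}": 35_000_000 for i in range(1, 5)})
    clones = [f"clone{i + 1}" for i in range(n_clones)]
    rt_loci = []
    per_chrom = -(-n_loci // 4)
    spacing = 33_000_000 // per_chrom
    size = locus_windows * 250_000
    for k in range(n_loci):
        chrom = f"chr{k % 4 + 1}"
        start = 1_000_000 + (k // 4) * spacing
        pattern = k % 3
        timing = {}
        for i, clone in enumerate(clones):
            if pattern == 0:
                timing[clone] = (EARLY if i % 2 == 0 else LATE, LATE)
            elif pattern == 1:
                timing[clone] = (LATE, EARLY if i % 2 == 0 else LATE)
            else:
                timing[clone] = (EARLY, LATE) if i % 2 == 0 else (LATE, EARLY)
        rt_loci.append(PlantedRTLocus(chrom, start, start + size, timing))
    return SimulationConfig(
        seed=seed, layout=layout, n_clones=n_clones, rt_loci=rt_loci, x_control=False
    )


def demo_config(seed: int = 0) -> SimulationConfig:
    """A small end-to-end scenario: planted TLs, coding genes, and RT loci.

    Plants six TLs spanning the expression-state vocabulary (constitutive
    mono-allelic, random epigenetic AEI with opposite homologs across
    clones, biallelic, clone-restricted silent), two coding genes, and
    three variable-timing loci, on the default five-chromosome layout with
    the X-like control enabled.
    """
    clones = [f"clone{i + 1}" for i in range(6)]
    half = {c: (MONO_HAP1 if i < 3 else MONO_HAP2) for i, c in enumerate(clones)}
    mixed = {
        clones[0]: MONO_HAP1, clones[1]: MONO_HAP2, clones[2]: BIALLELIC,
        clones[3]: SILENT, clones[4]: MONO_HAP1, clones[5]: MONO_HAP2,
    }
    tls = [
        PlantedLocus("chr1", 2_000_000, 2_100_000, "+", MONO_HAP1),
        PlantedLocus("chr1", 8_000_000, 8_080_000, "-", half),
        PlantedLocus("chr2", 5_000_000, 5_120_000, "+", mixed),
        PlantedLocus("chr2", 20_000_000, 20_060_000, "+", BIALLELIC),
        PlantedLocus("chr3", 11_000_000, 11_090_000, "-", BIALLELIC),
        PlantedLocus("chr4", 3_000_000, 3_070_000, "+", half),
    ]
    genes = [
        PlantedLocus("chr3", 22_000_000, 22_030_000, "+", half),
        PlantedLocus("chr4", 15_000_000, 15_040_000, "-", BIALLELIC),
    ]
    vary = {
        c: ((EARLY, LATE) if i % 2 == 0 else (LATE, LATE)) for i, c in enumerate(clones)
    }
    vary2 = {
        c: ((LATE, EARLY) if i < 2 else (EARLY, EARLY)) for i, c in enumerate(clones)
    }
    rt_loci = [
        PlantedRTLocus("chr1", 2_000_000, 2_750_000, vary),
        PlantedRTLocus("chr2", 5_000_000, 5_500_000, vary2),
        PlantedRTLocus("chr4", 3_000_000, 3_500_000, vary),
    ]
    return SimulationConfig(
        seed=seed, tls=tls, genes=genes, rt_loci=rt_loci, x_control=True
    )


# ---------------------------------------------------------------------------
# haplotype mirroring (symmetry checks)

def swap_haplotypes(dataset: SimulatedDataset) -> SimulatedDataset:
    """Mirror a dataset: exchange hap1/hap2 everywhere, truth included."""
    variants = [PhasedVariant(v.chrom, v.pos, v.hap2, v.hap1) for v in dataset.variants]
    swap_call = {HAP1: HAP2, HAP2: HAP1}
    reads = {
        clone: [
            replace(r, haplotype=swap_call.get(r.haplotype, r.haplotype))
            for r in clone_reads
        ]
        for clone, clone_reads in dataset.reads.items()
    }
    repliseq = dataset.repliseq.copy()
    repliseq["haplotype"] = repliseq["haplotype"].map(swap_call)
    repliseq = repliseq.sort_values(
        ["chrom", "start", "clone", "haplotype"], kind="stable"
    ).reset_index(drop=True)
    truth = dataset.truth
    expression = truth.expression.replace(_SWAP_STATE)
    rt_timing = truth.rt_timing.rename(columns={"hap1": "hap2", "hap2": "hap1"})[
        ["locus", "clone", "hap1", "hap2"]
    ]
    rt_windows = truth.rt_windows.copy()
    rt_windows["haplotype"] = rt_windows["haplotype"].map(swap_call)
    mirrored = GroundTruth(
        expression=expression,
        locus_info=truth.locus_info.copy(),
        random_aei=recompute_random_aei(expression),
        rt_loci=truth.rt_loci.copy(),
        rt_timing=rt_timing,
        vert=truth.vert.copy(),
        rt_windows=rt_windows,
    )
    return SimulatedDataset(dataset.config, variants, reads, repliseq, mirrored)


# ---------------------------------------------------------------------------
# on-disk emission (same dialects io_formats reads)

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit VCF, per-clone read TSVs, Repli-seq counts, and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_vcf(dataset, outdir / "variants.vcf")
    for clone, reads in dataset.reads.items():
        with open(outdir / f"reads_{clone}.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\tmapq\tdup\thap\n")
            for r in reads:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.mapq}\t"
                    f"{int(r.is_duplicate)}\t{_HAP_TSV[r.haplotype]}\n"
                )
    write_tsv(dataset.repliseq, outdir / "repliseq.tsv")
    truth = dataset.truth
    write_tsv(truth.locus_info, outdir / "truth_loci.tsv")
    expr = truth.expression.reset_index()
    write_tsv(expr, outdir / "truth_expression.tsv")
    write_tsv(
        truth.random_aei.rename("random_aei").reset_index(),
        outdir / "truth_random_aei.tsv",
    )
    write_tsv(truth.rt_timing, outdir / "truth_rt_timing.tsv")


def _write_vcf(dataset: SimulatedDataset, path: Path) -> None:
    layout = dataset.config.layout
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in layout:
            fh.write(f"##contig=<ID={chrom},length={layout.length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in dataset.variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.hap1}\t{v.hap2}\t.\tPASS\t.\tGT\t0|1\n"
            )
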