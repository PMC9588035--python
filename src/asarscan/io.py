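"""Readers/writers and the shared coordinate model.

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted from 1-based on load.  Two alignment sources are
supported and emit identical :class:`ReadRecord` streams: indexed BAM
(through pysam) and a simplified TSV read dialect with columns
``chrom start end strand mapq dup hap`` so that every desk-scale test can
run without BAM machinery.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# haplotype-call vocabulary
HAP1 = "hap1"
HAP2 = "hap2"
UNINFORMATIVE = "uninformative"
CONFLICTED = "conflicted"
HAPLOTYPE_CALLS = (HAP1, HAP2, UNINFORMATIVE, CONFLICTED)

_TSV_HAP = {"hap1": HAP1, "hap2": HAP2, "none": UNINFORMATIVE, "conflict": CONFLICTED}
_HAP_TSV = {v: k for k, v in _TSV_HAP.items()}

STRANDEDNESS = ("forward", "reverse")


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


@dataclass(frozen=True, order=True)
class PhasedVariant:
    """One phased heterozygous site; ``hap1`` is the allele left of '|'."""

    chrom: str
    pos: int  # 0-based
    hap1: str
    hap2: str

    def __post_init__(self) -> None:
        if self.hap1 == self.hap2:
            raise ValueError(f"variant at {self.chrom}:{self.pos} is not heterozygous")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned strand-specific read with an optional haplotype call."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    is_duplicate: bool = False
    haplotype: str = UNINFORMATIVE

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.chrom}:{self.start}-{self.end} is empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.haplotype not in HAPLOTYPE_CALLS:
            raise ValueError(f"bad haplotype call {self.haplotype!r}")


@dataclass(frozen=True)
class AnnotatedInterval:
    """A genomic annotation interval (gene, L1 repeat, other repeat...)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end} is empty")


@dataclass
class FilterStats:
    """Read-filter accounting: total = emitted + mapq + duplicate (+ skipped)."""

    total: int = 0
    emitted: int = 0
    mapq_filtered: int = 0
    duplicate_filtered: int = 0
    skipped: int = 0  # unmapped/secondary/supplementary (BAM only)


# ---------------------------------------------------------------------------
# VCF

def read_phased_vcf(path: str | Path) -> list[PhasedVariant]:
    """Load phased heterozygous biallelic sites from a VCF.

    Unphased, homozygous and multiallelic records are skipped (counts are
    logged).  ``hap1`` is the allele left of the phase separator.  Variants
    are returned sorted; a duplicated position within a chromosome keeps the
    first record only.
    """
    import pysam

    variants: list[PhasedVariant] = []
    skipped_unphased = skipped_hom = skipped_multi = 0
    with pysam.VariantFile(str(path)) as vcf:
        if len(vcf.header.samples) < 1:
            raise VcfParseError(f"{path}: VCF has no sample column")
        sample = vcf.header.samples[0]
        for rec in vcf:
            try:
                call = rec.samples[sample]
                if rec.alts is None or len(rec.alts) != 1:
                    skipped_multi += 1
                    logger.warning("multiallelic site %s:%s skipped", rec.chrom, rec.pos)
                    continue
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    skipped_unphased += 1
                    continue
                if not call.phased:
                    skipped_unphased += 1
                    continue
                a, b = gt
                if a == b:
                    skipped_hom += 1
                    continue
                alleles = rec.alleles
                variants.append(
                    PhasedVariant(rec.chrom, rec.start, alleles[a], alleles[b])
                )
            except VcfParseError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise VcfParseError(f"{path}: malformed record at {rec.chrom}:{rec.pos}: {exc}") from exc
    if skipped_unphased or skipped_hom or skipped_multi:
        logger.info(
            "read_phased_vcf(%s): skipped %d unphased, %d homozygous, %d multiallelic",
            path, skipped_unphased, skipped_hom, skipped_multi,
        )
    variants.sort()
    deduped: list[PhasedVariant] = []
    for v in variants:
        if deduped and deduped[-1].chrom == v.chrom and deduped[-1].pos == v.pos:
            logger.warning("duplicate position %s:%d, keeping first", v.chrom, v.pos)
            continue
        deduped.append(v)
    return deduped


# ---------------------------------------------------------------------------
# haplotype assignment

def assign_haplotype(
    observed_bases: Mapping[int, str],
    variants: Iterable[PhasedVariant],
) -> str:
    """Assign a read to a haplotype from the bases it shows at phased sites.

    ``observed_bases`` maps 0-based reference position -> base called by the
    read.  All overlapped variant bases matching hap1 -> ``hap1``; all
    matching hap2 -> ``hap2``; a mixture -> ``conflicted``; no overlapped
    variant, or bases matching neither allele -> ``uninformative``.
    """
    saw_h1 = saw_h2 = False
    for v in variants:
        base = observed_bases.get(v.pos)
        if base is None:
            continue
        if base == v.hap1:
            saw_h1 = True
        elif base == v.hap2:
            saw_h2 = True
    if saw_h1 and saw_h2:
        return CONFLICTED
    if saw_h1:
        return HAP1
    if saw_h2:
        return HAP2
    return UNINFORMATIVE


# ---------------------------------------------------------------------------
# alignments

def read_alignments(
    path: str | Path,
    mapq_min: int = 30,
    drop_duplicates: bool = True,
    strandedness: str = "reverse",
    variants: Sequence[PhasedVariant] | None = None,
    region: str | None = None,
) -> tuple[list[ReadRecord], FilterStats]:
    """Load alignments from BAM or the simplified TSV read dialect.

    Records failing ``mapq_min`` (exclusive: MAPQ below the threshold is
    removed, the threshold itself passes) or flagged duplicate are absent
    from the stream but counted in the returned :class:`FilterStats`.

    ``strandedness`` describes the library: ``"forward"`` means the read
    orientation is the transcript strand, ``"reverse"`` (dUTP-style, the
    default) means the transcript strand is the opposite of the alignment
    orientation.  The TSV dialect already stores transcript strand, so the
    setting applies to BAM input only.

    For BAM input, supplying ``variants`` turns on per-read haplotype
    assignment from the read bases at overlapped phased sites.
    """
    if strandedness not in STRANDEDNESS:
        raise ValueError(
            f"unknown strandedness {strandedness!r}; expected one of {STRANDEDNESS}"
        )
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        return _read_tsv_alignments(path, mapq_min, drop_duplicates)
    return _read_bam_alignments(
        path, mapq_min, drop_duplicates, strandedness, variants, region
    )


def _read_tsv_alignments(
    path: Path, mapq_min: int, drop_duplicates: bool
) -> tuple[list[ReadRecord], FilterStats]:
    stats = FilterStats()
    records: list[ReadRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            if len(row) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(row)}")
            chrom, start, end, strand, mapq, dup, hap = row[:7]
            stats.total += 1
            mapq_i = int(mapq)
            dup_b = dup not in ("0", "", "false", "False")
            if mapq_i < mapq_min:
                stats.mapq_filtered += 1
                continue
            if drop_duplicates and dup_b:
                stats.duplicate_filtered += 1
                continue
            if hap not in _TSV_HAP:
                raise ValueError(f"{path}:{lineno}: unknown hap field {hap!r}")
            records.append(
                ReadRecord(chrom, int(start), int(end), strand, mapq_i, dup_b, _TSV_HAP[hap])
            )
            stats.emitted += 1
    return records, stats


def _read_bam_alignments(
    path: Path,
    mapq_min: int,
    drop_duplicates: bool,
    strandedness: str,
    variants: Sequence[PhasedVariant] | None,
    region: str | None,
) -> tuple[list[ReadRecord], FilterStats]:
    import pysam

    by_chrom: dict[str, list[PhasedVariant]] = {}
    if variants:
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v)

    stats = FilterStats()
    records: list[ReadRecord] = []
    try:
        bam = pysam.AlignmentFile(str(path))
    except (ValueError, OSError) as exc:
        raise OSError(f"cannot open {path}: {exc}") from exc
    with bam:
        if region is not None and not bam.has_index():
            raise OSError(
                f"{path} has no index; run 'samtools index' before region queries"
            )
        it = bam.fetch(region=region) if region else bam.fetch(until_eof=True)
        for aln in it:
            stats.total += 1
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                stats.skipped += 1
                continue
            if aln.mapping_quality < mapq_min:
                stats.mapq_filtered += 1
                continue
            if drop_duplicates and aln.is_duplicate:
                stats.duplicate_filtered += 1
                continue
            strand = _transcript_strand(aln, strandedness)
            hap = UNINFORMATIVE
            chrom_vars = by_chrom.get(aln.reference_name)
            if chrom_vars:
                hap = _assign_from_alignment(aln, chrom_vars)
            records.append(
                ReadRecord(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    strand,
                    aln.mapping_quality,
                    aln.is_duplicate,
                    hap,
                )
            )
            stats.emitted += 1
    return records, stats


def _transcript_strand(aln, strandedness: str) -> str:
    # for paired data orient by read1; the mate reports the opposite strand
    forward = not aln.is_reverse
    if aln.is_paired and aln.is_read2:
        forward = not forward
    if strandedness == "reverse":
        forward = not forward
    return "+" if forward else "-"


def _assign_from_alignment(aln, chrom_vars: Sequence[PhasedVariant]) -> str:
    import bisect

    positions = [v.pos for v in chrom_vars]
    lo = bisect.bisect_left(positions, aln.reference_start)
    hi = bisect.bisect_left(positions, aln.reference_end)
    if lo == hi:
        return UNINFORMATIVE
    seq = aln.query_sequence
    if seq is None:
        return UNINFORMATIVE
    observed: dict[int, str] = {}
    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
        observed[rpos] = seq[qpos]
    return assign_haplotype(observed, chrom_vars[lo:hi])


# ---------------------------------------------------------------------------
# annotation input

def read_bed(path: str | Path, label: str = "other") -> list[AnnotatedInterval]:
    """Read BED3-6; column 4 becomes ``name``, column 6 ``strand``."""
    out: list[AnnotatedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(
                AnnotatedInterval(parts[0], int(parts[1]), int(parts[2]), strand, label, name)
            )
    return out


def read_repeat_bed(path: str | Path) -> list[AnnotatedInterval]:
    """RepeatMasker-style BED: chrom, start, end, name, family.

    The repeat family (column 5, falling back to the name) sets the class
    label: families starting with ``L1``/``LINE1``/``LINE/L1`` are labelled
    ``"L1 repeat"``, everything else ``"other repeat"``.
    """
    out: list[AnnotatedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else ""
            family = parts[4] if len(parts) > 4 else name
            fam = family.upper().replace("LINE/", "")
            label = "L1 repeat" if fam.startswith(("L1", "LINE1")) else "other repeat"
            out.append(
                AnnotatedInterval(parts[0], int(parts[1]), int(parts[2]), ".", label, name)
            )
    return out


def read_genes(path: str | Path) -> list[AnnotatedInterval]:
    """Read gene spans from BED6/BED12 or GTF/GFF3 (``gene`` features)."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        out: list[AnnotatedInterval] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8:
                    raise ValueError(f"{path}:{lineno}: GTF needs >=8 columns")
                if parts[2] != "gene":
                    continue
                strand = parts[6] if parts[6] in "+-" else "."
                out.append(
                    AnnotatedInterval(
                        parts[0], int(parts[3]) - 1, int(parts[4]), strand, "gene",
                        parts[8] if len(parts) > 8 else "",
                    )
                )
        return out
    return [replace(iv, label="gene") for iv in read_bed(path, label="gene")]


# ---------------------------------------------------------------------------
# output

def _check_sorted(intervals) -> None:
    prev = None
    for iv in intervals:
        key = (iv.chrom, iv.start)
        if prev is not None and key < prev:
            raise ValueError(
                f"intervals not sorted by chromosome then start at {iv.chrom}:{iv.start}"
            )
        prev = key


def write_bed(intervals: Sequence, path: str | Path) -> None:
    """Write BED (0-based half-open). Input must be sorted; no silent sorting."""
    intervals = list(intervals)
    _check_sorted(intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            name = getattr(iv, "name", "") or getattr(iv, "id", "")
            strand = getattr(iv, "strand", ".")
            if name or strand != ".":
                fields += [name or ".", "0", strand]
            fh.write("\t".join(fields) + "\n")


def _fmt_value(x: float) -> str:
    if x == 0:
        return "0"
    return f"{x:.6g}"


def write_bedgraph(
    profile: pd.DataFrame, path: str | Path, track_name: str | None = None
) -> None:
    """Write a bedGraph from a frame with chrom/start/end/value columns."""
    required = {"chrom", "start", "end", "value"}
    if not required.issubset(profile.columns):
        raise ValueError(f"profile needs columns {sorted(required)}")
    keys = list(zip(profile["chrom"], profile["start"]))
    if keys != sorted(keys):
        raise ValueError("profile not sorted by chromosome then start")
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for row in profile.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{_fmt_value(row.value)}\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)
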