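"""Integration and summary reporting: AEI x VERT overlaps and tallies.

Brings the per-stage results together into the headline summary surface:
per-dataset counts of transcribed loci, AEI loci (TL and coding), random
(opposite-homolog) AEI loci, VERT loci, and the AEI loci falling within
VERT regions.  Stages that were not run are reported as blanks, not
zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from asarscan.aei import AEIResults, OPPOSITE_HOMOLOGS

SUMMARY_COLUMNS = [
    "sample",
    "TLs",
    "AEI TLs",
    "AEI coding",
    "Random AEI TL",
    "Random AEI coding",
    "VERT loci",
    "AEI TL within VERT",
    "AEI coding within VERT",
]


def _vert_trees(vert: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in vert.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def overlap_aei_vert(
    loci: pd.DataFrame, vert: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Annotate loci with a ``within_vert`` flag.

    ``loci`` needs ``chrom, start, end`` columns (0-based half-open); a
    locus is within VERT when it overlaps any VERT locus by at least
    ``min_overlap`` bp.  Annotation is idempotent: re-annotating an already
    annotated frame recomputes the same flags.
    """
    trees = _vert_trees(vert)
    out = loci.copy()
    flags = []
    for row in out.itertuples(index=False):
        tree = trees.get(row.chrom)
        hit = False
        if tree is not None:
            for iv in tree.overlap(row.start, row.end):
                if min(iv.end, row.end) - max(iv.begin, row.start) >= min_overlap:
                    hit = True
                    break
        flags.append(hit)
    out["within_vert"] = flags
    return out


def overlap_with_bed(
    loci: pd.DataFrame, other: pd.DataFrame, column: str, min_overlap: int = 1
) -> pd.DataFrame:
    """Plain overlap annotation against a user-supplied interval set.

    Used e.g. to mark loci containing published rtQTL positions; no
    genetics is re-derived, this is interval intersection only.
    """
    annotated = overlap_aei_vert(loci, other, min_overlap)
    return annotated.rename(columns={"within_vert": column})


@dataclass
class SummaryTable:
    """One summary row per dataset; blanks (<NA>) mark unrun stages."""

    frame: pd.DataFrame

    def __str__(self) -> str:
        return self.frame.to_string(index=False)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_summary(
    aei: AEIResults,
    locus_info: pd.DataFrame,
    vert: pd.DataFrame | None = None,
    sample: str = "dataset",
    min_overlap: int = 1,
    chrom: str | None = None,
) -> SummaryTable:
    """Tally the headline per-dataset counts.

    Parameters
    ----------
    aei
        Fitted AEI results over TLs and coding genes (``kind`` column
        distinguishes the two families).
    locus_info
        ``locus, chrom, start, end`` coordinates for every locus in the
        AEI table (used for the VERT overlap).
    vert
        Union VERT loci (``chrom, start, end``); ``None`` leaves the
        VERT-dependent columns blank.
    chrom
        Restrict the tally to one chromosome (per-chromosome tallies sum
        to the genome-wide tally).
    """
    if aei is None:
        raise ValueError("AEI stage output is required to build a summary")
    if locus_info is None or not {"locus", "chrom", "start", "end"}.issubset(
        locus_info.columns
    ):
        raise ValueError("locus_info with locus/chrom/start/end is required")
    obs = aei.observations.merge(
        locus_info[["locus", "chrom", "start", "end"]], on="locus", how="left"
    )
    if obs["chrom"].isna().any():
        missing = obs.loc[obs["chrom"].isna(), "locus"].unique()[:5]
        raise ValueError(f"locus_info lacks coordinates for loci such as {list(missing)}")
    if chrom is not None:
        obs = obs[obs["chrom"] == chrom]

    def loci_of(kind: str, mask=None) -> pd.Index:
        sub = obs[obs["kind"] == kind]
        if mask is not None:
            sub = sub[mask(sub)]
        return pd.Index(sub["locus"].unique())

    tl_loci = loci_of("TL")
    aei_tl = loci_of("TL", lambda s: s["called"])
    aei_coding = loci_of("coding", lambda s: s["called"])
    random_map = aei.random_aei.set_index("locus")["category"] if len(aei.random_aei) else pd.Series(dtype=object)
    random_tl = pd.Index([l for l in tl_loci if random_map.get(l) == OPPOSITE_HOMOLOGS])
    coding_loci = loci_of("coding")
    random_coding = pd.Index(
        [l for l in coding_loci if random_map.get(l) == OPPOSITE_HOMOLOGS]
    )

    if vert is not None:
        vert_view = vert if chrom is None else vert[vert["chrom"] == chrom]
        coords = locus_info.drop_duplicates("locus").set_index("locus")
        def within(loci: pd.Index) -> int:
            if loci.empty:
                return 0
            frame = coords.loc[loci, ["chrom", "start", "end"]].reset_index()
            annotated = overlap_aei_vert(frame, vert_view, min_overlap)
            return int(annotated["within_vert"].sum())
        n_vert = len(vert_view)
        tl_within = within(aei_tl)
        coding_within = within(aei_coding)
    else:
        n_vert = tl_within = coding_within = pd.NA

    frame = pd.DataFrame(
        [
            {
                "sample": sample,
                "TLs": len(tl_loci),
                "AEI TLs": len(aei_tl),
                "AEI coding": len(aei_coding),
                "Random AEI TL": len(random_tl),
                "Random AEI coding": len(random_coding),
                "VERT loci": n_vert,
                "AEI TL within VERT": tl_within,
                "AEI coding within VERT": coding_within,
            }
        ],
        columns=SUMMARY_COLUMNS,
    )
    return SummaryTable(frame)
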