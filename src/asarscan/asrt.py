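"""Asynchronous replication timing (ASRT) regions and polarity coordination.

Within one clone, a window is asynchronous when the difference
d = RT_hap1 - RT_hap2 between the haplotype profiles is an outlier.  The
default rule interprets the "SD > 1" criterion as the two-allele standard
deviation per window: SD of {hap1, hap2} equals |d| / sqrt(2), so a window
is asynchronous when |d| > sqrt(2) log2 units.  An alternative z-score mode
flags |d| exceeding mean(|d|) + 1 SD(|d|) genome-wide.  Consecutive
asynchronous windows merge into ASRT regions, each carrying an Early/Late
polarity (which haplotype replicates earlier).

Coordination of polarity across regions — the "mirror-image" hypothesis —
is tested per chromosome or genome-wide: the statistic is the mean over
clones of the majority-orientation fraction among that clone's informative
regions (1 = perfectly coordinated, ~0.5 under independence), with a
permutation null that independently flips each region x clone polarity.
The skewed X serves as the positive control: its ASRT regions share one
polarity along the whole chromosome in every clone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from asarscan.io import HAP1, HAP2
from asarscan.layout import GenomeLayout
from asarscan.repli import RTResults, merge_outlier_windows

HAP1_EARLY = "hap1-early"
HAP2_EARLY = "hap2-early"
MISSING = "missing"

THRESHOLD_MODES = ("sd_gt_1", "z_gt_1")


def asrt_regions(
    profiles: pd.DataFrame | RTResults,
    mode: str = "sd_gt_1",
    max_join: int = 1,
) -> pd.DataFrame:
    """Detect per-clone asynchronous regions from haplotype RT profiles.

    ``profiles`` is the window x (clone, haplotype) matrix (or a fitted
    :class:`~asarscan.repli.RTResults`).  Both haplotype profiles must be
    present for every clone.  Returns ``clone, chrom, start, end,
    n_windows, mean_d, polarity`` rows.
    """
    if isinstance(profiles, RTResults):
        profiles = profiles.profiles
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"mode must be one of {THRESHOLD_MODES}, got {mode!r}")
    clones = sorted({c for c, _ in profiles.columns})
    windows = profiles.index.to_frame(index=False)
    out_frames = []
    for clone in clones:
        for hap in (HAP1, HAP2):
            if (clone, hap) not in profiles.columns:
                raise ValueError(f"clone {clone!r} lacks a {hap} profile")
        d = (profiles[(clone, HAP1)] - profiles[(clone, HAP2)]).to_numpy()
        abs_d = np.abs(d)
        if mode == "sd_gt_1":
            # SD of two values is |d|/sqrt(2); SD > 1  <=>  |d| > sqrt(2)
            flags = abs_d / np.sqrt(2.0) > 1.0
        else:
            ok = np.isfinite(abs_d)
            if ok.sum() < 2:
                flags = np.zeros_like(abs_d, dtype=bool)
            else:
                thr = abs_d[ok].mean() + abs_d[ok].std(ddof=1)
                flags = abs_d > thr
        flags = np.where(np.isfinite(d), flags, False).astype(bool)
        regions = merge_outlier_windows(windows, flags, max_join, scope=clone)
        if regions.empty:
            continue
        d_series = pd.Series(d, index=profiles.index)
        means = []
        for row in regions.itertuples(index=False):
            sel = d_series.loc[
                (d_series.index.get_level_values("chrom") == row.chrom)
                & (d_series.index.get_level_values("start") >= row.start)
                & (d_series.index.get_level_values("start") < row.end)
            ]
            means.append(float(sel.mean()))
        regions = regions.rename(columns={"scope": "clone"})
        regions["mean_d"] = means
        regions["polarity"] = np.where(
            regions["mean_d"] > 0, HAP1_EARLY, HAP2_EARLY
        )
        out_frames.append(regions)
    if not out_frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_windows", "clone", "mean_d", "polarity"]
        )
    return pd.concat(out_frames, ignore_index=True)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def polarity_matrix(
    regions: pd.DataFrame,
    clones: list[str] | None = None,
    min_reciprocal: float = 0.5,
) -> pd.DataFrame:
    """Match ASRT regions across clones into a consensus region x clone matrix.

    Regions from different clones are matched when they reciprocally
    overlap by at least ``min_reciprocal`` of each length (matching is
    against the first-seen member of a consensus cluster).  Entries are
    ``hap1-early`` / ``hap2-early``; clones without a matching region get
    ``missing``.  The index is (chrom, start, end) of the consensus span.
    """
    if clones is None:
        clones = sorted(regions["clone"].unique()) if len(regions) else []
    clusters: list[dict] = []
    for row in regions.sort_values(["chrom", "start"]).itertuples(index=False):
        span = (row.start, row.end)
        best = None
        best_ov = 0.0
        for cluster in clusters:
            if cluster["chrom"] != row.chrom:
                continue
            ov = _reciprocal_overlap(cluster["rep"], span)
            if ov >= min_reciprocal and ov > best_ov:
                best, best_ov = cluster, ov
        if best is None:
            clusters.append(
                dict(chrom=row.chrom, rep=span, lo=row.start, hi=row.end,
                     entries={row.clone: (row.polarity, 1.0)})
            )
        else:
            best["lo"] = min(best["lo"], row.start)
            best["hi"] = max(best["hi"], row.end)
            prev = best["entries"].get(row.clone)
            if prev is None or best_ov > prev[1]:
                best["entries"][row.clone] = (row.polarity, best_ov)
    index = pd.MultiIndex.from_tuples(
        [(c["chrom"], c["lo"], c["hi"]) for c in clusters],
        names=["chrom", "start", "end"],
    )
    data = {
        clone: [c["entries"].get(clone, (MISSING,))[0] for c in clusters]
        for clone in clones
    }
    return pd.DataFrame(data, index=index, columns=clones)


@dataclass
class CoordinationResult:
    """Polarity-coordination test result for one scope."""

    scope: str
    statistic: float
    p_value: float
    n_regions: int
    n_clones: int
    n_perm: int
    status: str  # 'ok' | 'inconclusive'

    def __str__(self) -> str:
        if self.status != "ok":
            return f"coordination[{self.scope}]: inconclusive ({self.n_regions} regions)"
        return (
            f"coordination[{self.scope}]: statistic={self.statistic:.3f} "
            f"p={self.p_value:.4g} ({self.n_regions} regions, {self.n_clones} clones)"
        )


def _signs(matrix: pd.DataFrame) -> np.ndarray:
    signs = np.full(matrix.shape, np.nan)
    values = matrix.to_numpy(dtype=object)
    signs[values == HAP1_EARLY] = 1.0
    signs[values == HAP2_EARLY] = -1.0
    return signs


def _statistic(signs: np.ndarray) -> float:
    # mean over clones of the majority-orientation fraction
    pos = np.sum(signs > 0, axis=0).astype(float)
    neg = np.sum(signs < 0, axis=0).astype(float)
    n_inf = pos + neg
    ok = n_inf > 0
    if not ok.any():
        return float("nan")
    frac = np.maximum(pos[ok], neg[ok]) / n_inf[ok]
    return float(frac.mean())


class CoordinationTest:
    """Permutation test for Early/Late polarity coordination.

    Takes the consensus polarity matrix (regions x clones, entries
    ``hap1-early`` / ``hap2-early`` / ``missing``) from
    :func:`polarity_matrix`.  The null flips each informative
    region x clone entry independently with probability 0.5, matching the
    hypothesis that each region's polarity is set independently.
    """

    def __init__(self, matrix: pd.DataFrame) -> None:
        self.matrix = matrix

    def fit(
        self,
        scope: str = "genome",
        chrom: str | None = None,
        n_perm: int = 9999,
        seed: int | None = None,
    ) -> CoordinationResult:
        matrix = self.matrix
        if chrom is not None:
            matrix = matrix[matrix.index.get_level_values("chrom") == chrom]
            scope = chrom
        signs = _signs(matrix)
        informative_regions = int(np.sum(np.any(np.isfinite(signs), axis=1)))
        n_clones = int(np.sum(np.any(np.isfinite(signs), axis=0)))
        if informative_regions < 2:
            return CoordinationResult(
                scope, float("nan"), float("nan"), informative_regions,
                n_clones, 0, "inconclusive",
            )
        observed = _statistic(signs)
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm,) + signs.shape)
        perm = signs[None, :, :] * flips
        pos = np.sum(perm > 0, axis=1).astype(float)
        neg = np.sum(perm < 0, axis=1).astype(float)
        n_inf = pos + neg
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_inf > 0, np.maximum(pos, neg) / np.where(n_inf > 0, n_inf, 1), np.nan)
        perm_stat = np.nanmean(frac, axis=1)
        p = (1 + int(np.sum(perm_stat >= observed - 1e-12))) / (1 + n_perm)
        return CoordinationResult(
            scope, observed, float(p), informative_regions, n_clones, n_perm, "ok"
        )

    def per_chromosome(
        self, n_perm: int = 9999, seed: int | None = None
    ) -> dict[str, CoordinationResult]:
        """Coordination tested within each chromosome separately."""
        results = {}
        ss = np.random.SeedSequence(seed)
        chroms = list(dict.fromkeys(self.matrix.index.get_level_values("chrom")))
        for child, chrom in zip(ss.spawn(len(chroms)), chroms):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            results[chrom] = self.fit(chrom=chrom, n_perm=n_perm, seed=sub_seed)
        return results


@dataclass
class XPolarityReport:
    """Within-clone polarity consistency on the X-control chromosome."""

    status: str                        # 'pass' | 'fail' | 'inconclusive'
    clone_consistent: dict[str, bool | None]
    flipped_regions: list[tuple]       # (chrom, start, end, clone) minority entries
    n_regions: int


def x_polarity_control(matrix: pd.DataFrame, layout: GenomeLayout) -> XPolarityReport:
    """Check that all informative X ASRT regions share one polarity per clone."""
    if layout.x_chromosome is None:
        raise ValueError("layout designates no X-control chromosome")
    sub = matrix[matrix.index.get_level_values("chrom") == layout.x_chromosome]
    consistent: dict[str, bool | None] = {}
    flipped: list[tuple] = []
    for clone in sub.columns:
        entries = sub[clone]
        informative = entries[entries.isin([HAP1_EARLY, HAP2_EARLY])]
        if informative.empty:
            consistent[clone] = None
            continue
        counts = informative.value_counts()
        majority = counts.idxmax()
        consistent[clone] = counts.size == 1
        for idx, val in informative.items():
            if val != majority:
                flipped.append((*idx, clone))
    informative_clones = [v for v in consistent.values() if v is not None]
    if not informative_clones:
        status = "inconclusive"
    elif all(informative_clones):
        status = "pass"
    else:
        status = "fail"
    return XPolarityReport(status, consistent, flipped, int(len(sub)))
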