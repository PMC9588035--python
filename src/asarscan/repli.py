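"""Allele-specific replication timing: profiles, SD_alleles, VERT loci.

Early/Late Repli-seq reads are enumerated per haplotype in non-overlapping
250-kb windows.  After quantile normalization of the count vectors, the
per-window replication timing value is log2((Early + c) / (Late + c)),
positive for early replication.  Epigenetic variation between alleles is
measured as SD_alleles, the standard deviation of the timing value across
contributing profiles in a scope:

* combined  — all clone x haplotype profiles;
* hap1 / hap2 (allele-restricted) — one haplotype's profiles across clones.

Windows are outliers when SD_alleles exceeds a genome-wide threshold,
center(SD) + k * SD(SD) with k = 2.5, computed over autosomal windows only
(the X is the internal control, not part of the null).  Consecutive
outlier windows merge into VERT (variable epigenetic replication timing)
loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from asarscan.io import CONFLICTED, HAP1, HAP2, UNINFORMATIVE
from asarscan.layout import GenomeLayout

SCOPES = ("combined", "hap1", "hap2")


def make_windows(layout: GenomeLayout, window: int = 250_000) -> pd.DataFrame:
    """Fixed non-overlapping window grid [k*w, (k+1)*w) per chromosome."""
    if not isinstance(window, (int, np.integer)) or window <= 0:
        raise ValueError(f"window size must be a positive integer, got {window!r}")
    rows = []
    for chrom in layout:
        n = layout.length(chrom) // window
        for k in range(n):
            rows.append((chrom, k * window, (k + 1) * window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_repliseq(
    reads: pd.DataFrame,
    layout: GenomeLayout,
    window: int = 250_000,
) -> pd.DataFrame:
    """Count haplotype-informative Repli-seq reads per window.

    ``reads`` is a long frame with columns ``chrom``, ``pos`` (0-based),
    ``clone``, ``haplotype`` and ``fraction`` (``early``/``late``).
    Uninformative and conflicted reads are excluded from allele-specific
    counts.  Returns the binned long frame ``chrom, start, end, clone,
    haplotype, early, late`` on the full window grid (zero-filled).
    """
    grid = make_windows(layout, window)
    informative = reads[reads["haplotype"].isin([HAP1, HAP2])].copy()
    informative = informative[
        informative["chrom"].isin(list(layout))
    ]
    informative["start"] = (informative["pos"] // window) * window
    counts = (
        informative.groupby(["chrom", "start", "clone", "haplotype", "fraction"])
        .size()
        .unstack("fraction", fill_value=0)
        .reset_index()
    )
    for frac in ("early", "late"):
        if frac not in counts.columns:
            counts[frac] = 0
    clones = sorted(reads["clone"].unique())
    scaffold = grid.merge(
        pd.MultiIndex.from_product(
            [clones, [HAP1, HAP2]], names=["clone", "haplotype"]
        ).to_frame(index=False),
        how="cross",
    )
    out = scaffold.merge(counts, on=["chrom", "start", "clone", "haplotype"], how="left")
    out["early"] = out["early"].fillna(0).astype(int)
    out["late"] = out["late"].fillna(0).astype(int)
    # clip windows beyond the grid (reads past the last full window)
    return out[["chrom", "start", "end", "clone", "haplotype", "early", "late"]]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization across columns (samples).

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; ties within a sample receive the mean of their rank
    range.  A constant (e.g. all-zero) sample cannot be normalized and
    raises.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization input must be complete")
    for j, col in enumerate(matrix.columns):
        if np.all(values[:, j] == values[0, j]):
            raise ValueError(f"sample {col!r} is constant and cannot be normalized")
    order_means = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy()
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, order_means)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rt_profile(
    early: np.ndarray | pd.Series,
    late: np.ndarray | pd.Series,
    pseudocount: float = 1.0,
    min_reads: int = 10,
    raw_total: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """log2((E + c) / (L + c)) with masking of thin windows.

    Windows whose (raw) Early + Late total is below ``min_reads`` are NaN;
    positive values are early replication.  ``raw_total`` supplies the
    pre-normalization totals for masking; by default E + L is used.
    """
    e = np.asarray(early, dtype=float)
    l = np.asarray(late, dtype=float)
    total = np.asarray(raw_total, dtype=float) if raw_total is not None else e + l
    value = np.log2((e + pseudocount) / (l + pseudocount))
    value[total < min_reads] = np.nan
    return value


def merge_outlier_windows(
    windows: pd.DataFrame, flags: np.ndarray, max_join: int = 1, scope: str = "combined"
) -> pd.DataFrame:
    """Merge consecutive outlier windows into loci.

    ``max_join`` is the maximum run (outliers plus bridged interior
    windows) step: gaps of up to ``max_join - 1`` non-outlier windows
    between outliers are absorbed.  Returns ``chrom, start, end, n_windows,
    scope`` rows.
    """
    rows = []
    flags = np.asarray(flags, dtype=bool)
    for chrom, group in windows.assign(flag=flags).groupby("chrom", sort=False):
        group = group.sort_values("start")
        run_start = run_end = None
        n_out = 0
        gap = 0
        for row in group.itertuples(index=False):
            if row.flag:
                if run_start is None:
                    run_start, run_end, n_out = row.start, row.end, 1
                else:
                    run_end = row.end
                    n_out += 1
                gap = 0
            elif run_start is not None:
                gap += 1
                if gap >= max_join:
                    rows.append((chrom, run_start, run_end, n_out, scope))
                    run_start = run_end = None
                    n_out = 0
                    gap = 0
        if run_start is not None:
            rows.append((chrom, run_start, run_end, n_out, scope))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows", "scope"])


class ReplicationTimingModel:
    """Allele-specific RT model over binned Early/Late counts.

    Parameters
    ----------
    counts
        Long frame ``chrom, start, end, clone, haplotype, early, late`` on
        a shared window grid (see :func:`bin_repliseq`; the synthetic
        generator emits this shape directly).
    layout
        Genome layout; the designated X chromosome is excluded from the
        outlier-threshold null.
    pseudocount, min_reads
        Guards of the log ratio: log2((E+c)/(L+c)), windows with fewer than
        ``min_reads`` raw reads masked.
    quantile_normalization
        ``"joint"`` (default) normalizes all Early and Late vectors of all
        profiles together, ``"per-fraction"`` normalizes Early vectors and
        Late vectors separately, ``None`` skips normalization.
    smooth
        Optional moving-average half-window (in windows); 0 disables.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        layout: GenomeLayout,
        *,
        pseudocount: float = 1.0,
        min_reads: int = 10,
        quantile_normalization: str | None = "joint",
        smooth: int = 0,
    ) -> None:
        required = {"chrom", "start", "end", "clone", "haplotype", "early", "late"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"counts lack columns {sorted(missing)}")
        if quantile_normalization not in ("joint", "per-fraction", None):
            raise ValueError(f"bad quantile_normalization {quantile_normalization!r}")
        self.counts = counts.copy()
        self.layout = layout
        self.pseudocount = float(pseudocount)
        self.min_reads = int(min_reads)
        self.quantile_normalization = quantile_normalization
        self.smooth = int(smooth)

    def _pivot(self, column: str) -> pd.DataFrame:
        wide = self.counts.pivot_table(
            index=["chrom", "start", "end"],
            columns=["clone", "haplotype"],
            values=column,
            aggfunc="sum",
        )
        return wide.sort_index()

    def profiles(self) -> pd.DataFrame:
        """Window x (clone, haplotype) matrix of masked log2(E/L) values."""
        early = self._pivot("early")
        late = self._pivot("late")
        raw_total = early + late
        if self.quantile_normalization == "joint":
            stacked = pd.concat(
                {"early": early, "late": late}, axis=1
            )  # fraction level on top
            normed = quantile_normalize(stacked)
            early_n = normed["early"]
            late_n = normed["late"]
        elif self.quantile_normalization == "per-fraction":
            early_n = quantile_normalize(early)
            late_n = quantile_normalize(late)
        else:
            early_n, late_n = early.astype(float), late.astype(float)
        values = pd.DataFrame(
            index=early.index, columns=early.columns, dtype=float
        )
        for col in early.columns:
            values[col] = rt_profile(
                early_n[col], late_n[col], self.pseudocount, self.min_reads,
                raw_total=raw_total[col],
            )
        if self.smooth > 0:
            k = 2 * self.smooth + 1
            values = values.groupby(level="chrom", sort=False).transform(
                lambda s: s.rolling(k, center=True, min_periods=1).mean()
            )
        return values

    def fit(
        self,
        scopes: Sequence[str] = SCOPES,
        center: str = "mean",
        k: float = 2.5,
        max_join: int = 1,
    ) -> "RTResults":
        """Compute SD_alleles per scope, thresholds, outliers and VERT loci.

        ``center`` selects mean (default) or median of the genome-wide
        autosomal SD_alleles distribution for the outlier threshold
        center; ``k`` scales its standard deviation.
        """
        if center not in ("mean", "median"):
            raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
        for scope in scopes:
            if scope not in SCOPES:
                raise ValueError(f"unknown scope {scope!r}")
        profiles = self.profiles()
        windows = profiles.index.to_frame(index=False)
        autosomal = windows["chrom"] != self.layout.x_chromosome

        sd_frames: dict[str, pd.Series] = {}
        thresholds: dict[str, float] = {}
        outliers: dict[str, np.ndarray] = {}
        vert_frames = []
        for scope in scopes:
            if scope == "combined":
                cols = list(profiles.columns)
            else:
                cols = [c for c in profiles.columns if c[1] == scope]
            sub = profiles[cols]
            n_ok = sub.notna().sum(axis=1)
            sd = sub.std(axis=1, ddof=1)
            sd[n_ok < 2] = np.nan
            sd_frames[scope] = sd
            null_sd = sd[autosomal.to_numpy() & sd.notna().to_numpy()]
            if null_sd.empty:
                thresholds[scope] = np.nan
                outliers[scope] = np.zeros(len(sd), dtype=bool)
                continue
            c = null_sd.mean() if center == "mean" else null_sd.median()
            spread = null_sd.std(ddof=1)
            thr = float(c + k * spread)
            thresholds[scope] = thr
            if not np.isfinite(thr) or spread < 1e-12:
                # degenerate null (identical profiles): no outlier notion
                outliers[scope] = np.zeros(len(sd), dtype=bool)
                continue
            flags = (sd >= thr).fillna(False).to_numpy()
            outliers[scope] = flags
            vert_frames.append(merge_outlier_windows(windows, flags, max_join, scope))
        vert = (
            pd.concat(vert_frames, ignore_index=True)
            if vert_frames
            else pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "scope"])
        )
        return RTResults(
            self, profiles, pd.DataFrame(sd_frames), thresholds, outliers, vert,
            center=center, k=k, max_join=max_join,
        )


class RTResults:
    """Fitted replication-timing results.

    Attributes
    ----------
    profiles
        Window x (clone, haplotype) log2(E/L) matrix (NaN = masked).
    sd
        Window x scope SD_alleles matrix.
    thresholds
        Scope -> outlier threshold (center + k * SD of the autosomal
        SD_alleles distribution).
    vert
        Per-scope merged outlier loci (``chrom, start, end, n_windows,
        scope``).
    """

    def __init__(
        self,
        model: ReplicationTimingModel,
        profiles: pd.DataFrame,
        sd: pd.DataFrame,
        thresholds: dict[str, float],
        outliers: dict[str, np.ndarray],
        vert: pd.DataFrame,
        center: str,
        k: float,
        max_join: int,
    ) -> None:
        self.model = model
        self.profiles = profiles
        self.sd = sd
        self.thresholds = thresholds
        self.outliers = outliers
        self.vert = vert
        self.center = center
        self.k = k
        self.max_join = max_join

    @property
    def windows(self) -> pd.DataFrame:
        return self.profiles.index.to_frame(index=False)

    def profile(self, clone: str, haplotype: str) -> pd.Series:
        """One clone+haplotype RT profile indexed by (chrom, start, end)."""
        return self.profiles[(clone, haplotype)]

    def vert_loci(self, scope: str | None = None) -> pd.DataFrame:
        """Merged VERT loci for a scope, or the cross-scope union.

        The union merges overlapping loci from different scopes into one
        interval carrying the joined scope labels.
        """
        if scope is not None:
            return self.vert[self.vert["scope"] == scope].reset_index(drop=True)
        rows = []
        for chrom, group in self.vert.groupby("chrom", sort=False):
            group = group.sort_values("start")
            cur = None
            for row in group.itertuples(index=False):
                if cur is None or row.start >= cur[1]:
                    if cur is not None:
                        rows.append((chrom, *cur))
                    cur = [row.start, row.end, {row.scope}]
                else:
                    cur[1] = max(cur[1], row.end)
                    cur[2].add(row.scope)
            if cur is not None:
                rows.append((chrom, *cur))
        out = pd.DataFrame(rows, columns=["chrom", "start", "end", "scopes"])
        if len(out):
            out["scopes"] = out["scopes"].map(lambda s: ",".join(sorted(s)))
        return out

    def to_bedgraph_frame(self, clone: str, haplotype: str) -> pd.DataFrame:
        """chrom/start/end/value frame for io.write_bedgraph (masked dropped)."""
        series = self.profile(clone, haplotype)
        frame = series.rename("value").reset_index()
        return frame[frame["value"].notna()].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Allele-specific replication timing",
            "=" * 60,
            f"windows:         {len(self.profiles)}",
            f"profiles:        {self.profiles.shape[1]} (clone x haplotype)",
            f"threshold rule:  {self.center} + {self.k} x SD (autosomal windows)",
        ]
        for scope, thr in self.thresholds.items():
            n_out = int(self.outliers[scope].sum())
            n_loci = int((self.vert["scope"] == scope).sum())
            lines.append(
                f"{scope:<10} threshold {thr:.3f}  outlier windows {n_out:>4}"
                f"  merged loci {n_loci:>3}"
            )
        lines.append(f"VERT loci (union of scopes): {len(self.vert_loci())}")
        return "\n".join(lines)
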