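"""Allelic expression imbalance (AEI): statistic, outlier calling, states.

The AEI statistic for a locus in a clone is

    AEI = max(hap1 reads, hap2 reads) / total informative reads x 100

so perfect allelic balance gives 50 and complete bias toward one haplotype
gives 100.  A locus x clone observation is called AEI by combining two
outlier criteria over the whole run:

* parametric — exact two-sided binomial test against a null proportion of
  0.5, requiring p <= 0.001 and Benjamini-Hochberg q <= 0.01 (the BH family
  is all observations passing the informative-read floor, with TLs and
  coding genes corrected as separate families);
* non-parametric — ordinary least squares of AEI on log10(informative
  reads) over all tested observations, flagging observations whose
  residual exceeds 2.5 times the null residual spread at their expression
  level.  Both criteria estimate the null distribution of bi-allelic
  expression, so the spread is taken from the observations the parametric
  criterion did not flag (the null proxy), robustly (1.4826 x MAD) within
  log-depth deciles with a global fallback for thin bins.  Estimating the
  spread from all observations instead lets strong-AEI loci inflate their
  own yardstick: with a fraction f of extreme outliers in the scale
  estimate, the attainable standardized residual caps at sqrt((1-f)/f),
  below 2.5 once f exceeds ~14% — and mono-allelic loci concentrate in
  the low-depth bins because they carry half the informative reads of a
  bi-allelic locus at equal expression.  ``robust_scale=False`` switches
  MAD to the plain SD of the null subset.

The two flags are combined by intersection (default) or union.  Per-clone
expression states (mono-hap1 / mono-hap2 / biallelic / silent) follow from
the call, and loci showing mono-allelic expression of opposite homologs in
two or more clones are classified as random (epigenetic) AEI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from asarscan.layout import GenomeLayout
from asarscan.simulate import BIALLELIC, MONO_HAP1, MONO_HAP2, SILENT

logger = logging.getLogger(__name__)

OPPOSITE_HOMOLOGS = "opposite-homologs"
SINGLE_ALLELE_ONLY = "single-allele-only"
NOT_AEI = "not-AEI"


@dataclass(frozen=True)
class AlleleCounts:
    """Haplotype-informative read counts at one locus in one clone."""

    hap1: int
    hap2: int

    def __post_init__(self) -> None:
        if self.hap1 < 0 or self.hap2 < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.hap1 + self.hap2


def compute_aei(hap1: int, hap2: int) -> tuple[float, str]:
    """AEI percent (50-100) and favored haplotype ('none' on a tie).

    A zero total is undefined and returns (nan, 'none'); callers flag the
    observation as insufficient.
    """
    total = hap1 + hap2
    if total == 0:
        return float("nan"), "none"
    value = max(hap1, hap2) / total * 100.0
    if hap1 > hap2:
        favored = "hap1"
    elif hap2 > hap1:
        favored = "hap2"
    else:
        favored = "none"
    return value, favored


def binomial_pvalue(hap1: int, hap2: int) -> float:
    """Exact two-sided binomial p against a 0.5 null (minimum-likelihood)."""
    return stats.binomtest(hap1, hap1 + hap2, 0.5).pvalue


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_aei(parametric: bool, nonparametric: bool, combinator: str = "intersection") -> bool:
    """Combine the two outlier flags into one AEI call."""
    if combinator == "intersection":
        return parametric and nonparametric
    if combinator == "union":
        return parametric or nonparametric
    raise ValueError(f"combinator must be 'intersection' or 'union', got {combinator!r}")


def classify_clone_state(
    hap1: int, hap2: int, aei_called: bool, favored: str, min_informative: int = 20
) -> str:
    """Per-clone expression state from counts and the AEI call."""
    if hap1 + hap2 < min_informative:
        return SILENT
    if aei_called and favored == "hap1":
        return MONO_HAP1
    if aei_called and favored == "hap2":
        return MONO_HAP2
    return BIALLELIC


def detect_random_aei(states: Iterable[str]) -> str:
    """Cross-clone category for one locus from its per-clone states."""
    states = list(states)
    if len(states) < 2:
        raise ValueError("random-AEI detection needs >=2 clones")
    has1 = MONO_HAP1 in states
    has2 = MONO_HAP2 in states
    if has1 and has2:
        return OPPOSITE_HOMOLOGS
    if has1 or has2:
        return SINGLE_ALLELE_ONLY
    return NOT_AEI


@dataclass
class XSkewReport:
    """Orientation consistency of AEI on the X-control chromosome."""

    status: str                       # 'pass' | 'fail' | 'inconclusive'
    clone_orientation: dict[str, str]          # clone -> 'hap1'/'hap2'/'none'
    clone_hap1_fraction: dict[str, float]      # among AEI-called X loci
    n_called: int


class AEIModel:
    """Allelic-expression-imbalance model over a locus x clone count table.

    Parameters
    ----------
    data
        Long-format frame with columns ``locus``, ``clone``, ``hap1``,
        ``hap2`` and optionally ``kind`` (``"TL"`` or ``"coding"``;
        defaults to ``"TL"``).  Counts are haplotype-informative reads;
        conflicted/uninformative reads are already excluded.
    min_informative
        Read floor below which an observation is untested (silent /
        insufficient) and excluded from the BH family.
    alpha_p, alpha_q
        Binomial p and BH q thresholds of the parametric criterion.
    combinator
        ``"intersection"`` (default) or ``"union"`` of the two criteria.
    k_sd
        Residual threshold of the non-parametric criterion, in residual-SD
        units at the observation's expression level.
    min_regression_obs
        Minimum tested observations needed to fit the regression; below it
        the non-parametric criterion is disabled with a warning and calls
        fall back to the parametric flag alone.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        min_informative: int = 20,
        alpha_p: float = 0.001,
        alpha_q: float = 0.01,
        combinator: str = "intersection",
        k_sd: float = 2.5,
        min_regression_obs: int = 50,
        n_depth_bins: int = 10,
        min_bin_obs: int = 20,
        robust_scale: bool = True,
    ) -> None:
        required = {"locus", "clone", "hap1", "hap2"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns {sorted(missing)}")
        if combinator not in ("intersection", "union"):
            raise ValueError(f"bad combinator {combinator!r}")
        self.data = data.copy()
        if "kind" not in self.data.columns:
            self.data["kind"] = "TL"
        self.min_informative = int(min_informative)
        self.alpha_p = float(alpha_p)
        self.alpha_q = float(alpha_q)
        self.combinator = combinator
        self.k_sd = float(k_sd)
        self.min_regression_obs = int(min_regression_obs)
        self.n_depth_bins = int(n_depth_bins)
        self.min_bin_obs = int(min_bin_obs)
        self.robust_scale = bool(robust_scale)

    @classmethod
    def from_reads(
        cls,
        loci: Sequence,
        reads_by_clone: Mapping[str, Sequence],
        kind: str = "TL",
        **kwargs,
    ) -> "AEIModel":
        """Build the count table from loci and per-clone read records."""
        from asarscan.tl import count_reads_by_locus

        counts = count_reads_by_locus(loci, reads_by_clone)
        counts["kind"] = kind
        return cls(counts, **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "AEIResults":
        obs = self.data.copy()
        obs["total"] = obs["hap1"] + obs["hap2"]
        obs["tested"] = obs["total"] >= self.min_informative

        aei = np.full(len(obs), np.nan)
        favored = np.full(len(obs), "none", dtype=object)
        nz = obs["total"].to_numpy() > 0
        h1 = obs["hap1"].to_numpy(dtype=float)
        h2 = obs["hap2"].to_numpy(dtype=float)
        tot = obs["total"].to_numpy(dtype=float)
        aei[nz] = np.maximum(h1[nz], h2[nz]) / tot[nz] * 100.0
        favored[nz & (h1 > h2)] = "hap1"
        favored[nz & (h2 > h1)] = "hap2"
        obs["aei"] = aei
        obs["favored"] = favored

        obs["p_value"] = np.nan
        obs["q_value"] = np.nan
        tested_idx = obs.index[obs["tested"]]
        h1_t = obs.loc[tested_idx, "hap1"].to_numpy()
        h2_t = obs.loc[tested_idx, "hap2"].to_numpy()
        obs.loc[tested_idx, "p_value"] = [
            binomial_pvalue(int(a), int(b)) for a, b in zip(h1_t, h2_t)
        ]
        for _, group in obs.loc[tested_idx].groupby("kind"):
            obs.loc[group.index, "q_value"] = bh_qvalues(group["p_value"].to_numpy())
        obs["parametric"] = (
            obs["tested"]
            & (obs["p_value"] <= self.alpha_p)
            & (obs["q_value"] <= self.alpha_q)
        )

        obs["residual_z"], nonparam_enabled = self._regression_outliers(obs)
        if nonparam_enabled:
            obs["nonparametric"] = obs["tested"] & (obs["residual_z"] >= self.k_sd)
        else:
            obs["nonparametric"] = False

        if not nonparam_enabled:
            combined = obs["parametric"]
        elif self.combinator == "intersection":
            combined = obs["parametric"] & obs["nonparametric"]
        else:
            combined = obs["parametric"] | obs["nonparametric"]
        obs["called"] = combined & obs["tested"] & (obs["favored"] != "none")

        state = np.where(
            ~obs["tested"], SILENT,
            np.where(
                obs["called"] & (obs["favored"] == "hap1"), MONO_HAP1,
                np.where(obs["called"] & (obs["favored"] == "hap2"), MONO_HAP2, BIALLELIC),
            ),
        )
        obs["state"] = state

        random_aei = self._random_aei(obs)
        return AEIResults(self, obs, random_aei, nonparam_enabled)

    def _regression_outliers(self, obs: pd.DataFrame) -> tuple[np.ndarray, bool]:
        """Standardized AEI residuals versus log10 expression, per decile."""
        import statsmodels.api as sm

        z = np.zeros(len(obs))
        tested = obs["tested"].to_numpy()
        n_tested = int(tested.sum())
        if n_tested < self.min_regression_obs:
            logger.warning(
                "only %d tested observations (< %d); non-parametric criterion disabled",
                n_tested, self.min_regression_obs,
            )
            return z, False
        sub = obs.loc[tested]
        x = np.log10(sub["total"].to_numpy(dtype=float))
        y = sub["aei"].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        resid = y - fit.fittedvalues
        null_mask = ~sub["parametric"].to_numpy(dtype=bool)

        if self.robust_scale:
            def scale(v: np.ndarray) -> float:
                return 1.4826 * float(np.median(np.abs(v - np.median(v))))
        else:
            def scale(v: np.ndarray) -> float:
                return float(np.std(v, ddof=1)) if v.size > 1 else float("nan")

        if null_mask.sum() < 2:
            return z, True
        global_sd = scale(resid[null_mask])
        if not np.isfinite(global_sd) or global_sd <= 0:
            # degenerate run (all null observations share one AEI): no outliers
            return z, True
        sd = np.full(resid.size, global_sd)
        try:
            bins = pd.qcut(x, self.n_depth_bins, duplicates="drop")
        except ValueError:
            bins = None
        if bins is not None and bins.categories.size > 1:
            codes = np.asarray(bins.codes)
            for b in np.unique(codes):
                in_bin = codes == b
                null_in_bin = in_bin & null_mask
                if null_in_bin.sum() >= self.min_bin_obs:
                    s = scale(resid[null_in_bin])
                    if np.isfinite(s) and s > 0:
                        sd[in_bin] = s
        z[tested] = resid / sd
        return z, True

    def _random_aei(self, obs: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for locus, group in obs.groupby("locus", sort=False):
            if len(group) < 2:
                continue
            category = detect_random_aei(group["state"])
            rows.append((locus, category, category == OPPOSITE_HOMOLOGS))
        return pd.DataFrame(rows, columns=["locus", "category", "random_aei"])


class AEIResults:
    """Fitted AEI results: per-observation calls and cross-clone categories.

    Attributes
    ----------
    observations
        Long frame with the input counts plus ``aei``, ``favored``,
        ``p_value``, ``q_value``, ``residual_z``, ``parametric``,
        ``nonparametric``, ``called`` and ``state`` columns.
    random_aei
        Per-locus frame with the cross-clone ``category`` and the
        ``random_aei`` (opposite-homologs) flag.
    """

    def __init__(
        self,
        model: AEIModel,
        observations: pd.DataFrame,
        random_aei: pd.DataFrame,
        nonparametric_enabled: bool,
    ) -> None:
        self.model = model
        self.observations = observations
        self.random_aei = random_aei
        self.nonparametric_enabled = nonparametric_enabled

    # -- convenience views ----------------------------------------------

    def states_wide(self) -> pd.DataFrame:
        """locus x clone matrix of expression states."""
        return self.observations.pivot(index="locus", columns="clone", values="state")

    def called_loci(self, kind: str | None = None) -> list[str]:
        """Loci with an AEI call in at least one clone."""
        obs = self.observations
        if kind is not None:
            obs = obs[obs["kind"] == kind]
        called = obs.loc[obs["called"], "locus"].unique()
        return list(called)

    def x_skew_control(
        self, locus_chrom: Mapping[str, str], layout: GenomeLayout
    ) -> XSkewReport:
        """Check same-orientation AEI across clones on the X-like chromosome.

        Escape-like biallelic loci carry no call and therefore do not vote;
        a clone's orientation is the haplotype favored by its AEI-called X
        loci.  Status is ``pass`` when every clone with calls agrees on one
        haplotype and at least one clone has calls, ``fail`` when clones
        disagree (or one clone's own calls split), ``inconclusive`` with no
        calls at all.
        """
        if layout.x_chromosome is None:
            raise ValueError("layout designates no X-control chromosome")
        obs = self.observations
        on_x = obs["locus"].map(locus_chrom) == layout.x_chromosome
        sub = obs[on_x & obs["called"]]
        orientation: dict[str, str] = {}
        fraction: dict[str, float] = {}
        for clone, group in obs[on_x].groupby("clone"):
            called = group[group["called"]]
            if called.empty:
                orientation[clone] = "none"
                fraction[clone] = float("nan")
                continue
            f1 = float((called["favored"] == "hap1").mean())
            fraction[clone] = f1
            if f1 == 1.0:
                orientation[clone] = "hap1"
            elif f1 == 0.0:
                orientation[clone] = "hap2"
            else:
                orientation[clone] = "mixed"
        informative = [o for o in orientation.values() if o != "none"]
        if not informative:
            status = "inconclusive"
        elif "mixed" in informative or len(set(informative)) > 1:
            status = "fail"
        else:
            status = "pass"
        return XSkewReport(status, orientation, fraction, int(len(sub)))

    def summary(self) -> str:
        obs = self.observations
        tested = obs["tested"]
        lines = [
            "Allelic expression imbalance",
            "=" * 60,
            f"observations:          {len(obs)}",
            f"tested (>= {self.model.min_informative} reads):  {int(tested.sum())}",
            f"AEI calls:             {int(obs['called'].sum())}"
            f"  (combinator: {self.model.combinator})",
            f"loci with AEI:         {len(self.called_loci())}",
            f"non-parametric fit:    {'enabled' if self.nonparametric_enabled else 'disabled'}",
        ]
        if len(self.random_aei):
            counts = self.random_aei["category"].value_counts()
            for cat in (OPPOSITE_HOMOLOGS, SINGLE_ALLELE_ONLY, NOT_AEI):
                lines.append(f"{cat + ':':<23}{int(counts.get(cat, 0))}")
        return "\n".join(lines)
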