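"""AEI statistic, binomial/BH machinery, regression outliers, states."""

import numpy as np
import pandas as pd
import pytest

from asarscan.aei import (
    NOT_AEI,
    OPPOSITE_HOMOLOGS,
    SINGLE_ALLELE_ONLY,
    AEIModel,
    AlleleCounts,
    bh_qvalues,
    binomial_pvalue,
    call_aei,
    classify_clone_state,
    compute_aei,
    detect_random_aei,
)
from asarscan.layout import GenomeLayout
from asarscan.simulate import (
    BIALLELIC,
    MONO_HAP1,
    MONO_HAP2,
    SILENT,
    simulate_aei_table,
)


class TestComputeAei:
    @pytest.mark.parametrize(
        "h1,h2,value,favored",
        [
            (100, 100, 50.0, "none"),   # perfect balance
            (20, 0, 100.0, "hap1"),     # complete bias
            (15, 5, 75.0, "hap1"),
            (5, 15, 75.0, "hap2"),
        ],
    )
    def test_statistic(self, h1, h2, value, favored):
        got_value, got_favored = compute_aei(h1, h2)
        assert got_value == pytest.approx(value)
        assert got_favored == favored

    def test_zero_total_undefined(self):
        value, favored = compute_aei(0, 0)
        assert np.isnan(value) and favored == "none"

    def test_allele_counts_validation(self):
        assert AlleleCounts(3, 4).total == 7
        with pytest.raises(ValueError):
            AlleleCounts(-1, 4)


class TestBinomial:
    def test_complete_bias_closed_form(self):
        # two-sided exact test at k=n, p0=0.5: p = 2 * 0.5^n
        assert binomial_pvalue(20, 0) == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_balanced_counts_p_one(self):
        assert binomial_pvalue(10, 10) == pytest.approx(1.0)

    def test_symmetry(self):
        assert binomial_pvalue(63, 37) == pytest.approx(binomial_pvalue(37, 63))


def _bh_oracle(pvals):
    # textbook step-up: q_(i) = min_{k >= i} m * p_(k) / k
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = bh_qvalues([0.001, 0.02, 0.9])
        assert q == pytest.approx([0.003, 0.03, 0.9])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        p = rng.uniform(0, 1, size=int(rng.integers(1, 200)))
        assert bh_qvalues(p) == pytest.approx(_bh_oracle(p), rel=1e-12)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, size=500)
        q = bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallCombinator:
    @pytest.mark.parametrize(
        "flags,combinator,expected",
        [
            ((True, False), "union", True),
            ((True, False), "intersection", False),
            ((False, False), "union", False),
            ((False, False), "intersection", False),
            ((True, True), "intersection", True),
        ],
    )
    def test_truth_table(self, flags, combinator, expected):
        assert call_aei(*flags, combinator) is expected

    def test_unknown_combinator(self):
        with pytest.raises(ValueError):
            call_aei(True, True, "xor")


class TestStateClassification:
    @pytest.mark.parametrize(
        "h1,h2,called,favored,state",
        [
            (25, 0, True, "hap1", MONO_HAP1),
            (0, 25, True, "hap2", MONO_HAP2),
            (10, 9, True, "hap1", SILENT),       # 19 < 20 informative
            (50, 50, False, "none", BIALLELIC),
            (40, 20, False, "hap1", BIALLELIC),  # tested but not called
        ],
    )
    def test_states(self, h1, h2, called, favored, state):
        assert classify_clone_state(h1, h2, called, favored) == state


class TestRandomAei:
    @pytest.mark.parametrize(
        "states,category",
        [
            ([MONO_HAP1, MONO_HAP2, BIALLELIC, SILENT], OPPOSITE_HOMOLOGS),
            ([MONO_HAP1, MONO_HAP1], SINGLE_ALLELE_ONLY),
            ([BIALLELIC, BIALLELIC], NOT_AEI),
            ([SILENT, BIALLELIC], NOT_AEI),
        ],
    )
    def test_categories(self, states, category):
        assert detect_random_aei(states) == category

    def test_requires_two_clones(self):
        with pytest.raises(ValueError):
            detect_random_aei([MONO_HAP1])


def _fit_table(obs, **kwargs):
    return AEIModel(obs, **kwargs).fit()


class TestAEIModelFit:
    def test_recovers_planted_states(self):
        obs, truth = simulate_aei_table(seed=21, n_null=450, n_mono=50, n_clones=4)
        results = _fit_table(obs)
        merged = results.observations.merge(truth, on=["locus", "clone"])
        mono = merged[merged["state_y"].isin([MONO_HAP1, MONO_HAP2])]
        agreement = (mono["state_x"] == mono["state_y"]).mean()
        assert agreement >= 0.9
        # biallelic loci essentially never called
        null = merged[merged["state_y"] == BIALLELIC]
        assert (null["state_x"].isin([MONO_HAP1, MONO_HAP2])).mean() <= 0.01

    def test_regression_outlier_flagged_against_ols_oracle(self):
        rng = np.random.default_rng(4)
        depth = rng.integers(80, 320, size=501)
        h1 = rng.binomial(depth[:-1], 0.5)
        rows = [("L%d" % i, "c1", "TL", int(a), int(d - a)) for i, (a, d) in enumerate(zip(h1, depth[:-1]))]
        rows.append(("Lout", "c1", "TL", int(depth[-1]), 0))  # AEI 100 at matched depth
        obs = pd.DataFrame(rows, columns=["locus", "clone", "kind", "hap1", "hap2"])
        results = _fit_table(obs)
        table = results.observations.set_index("locus")
        assert bool(table.loc["Lout", "nonparametric"])
        assert bool(table.loc["Lout", "called"])
        # independent least-squares oracle for the fitted line
        sub = table[table["tested"]]
        slope, intercept = np.polyfit(np.log10(sub["total"]), sub["aei"], 1)
        predicted = intercept + slope * np.log10(table.loc["Lout", "total"])
        assert table.loc["Lout", "aei"] - predicted > 2.5 * sub["aei"].std(ddof=1) * 0.1

    def test_zero_variance_guard(self):
        obs = pd.DataFrame(
            {
                "locus": [f"L{i}" for i in range(60)],
                "clone": "c1",
                "hap1": 50,
                "hap2": 50,
            }
        )
        results = _fit_table(obs)
        assert not results.observations["nonparametric"].any()
        assert not results.observations["called"].any()

    def test_few_observations_disable_nonparametric(self):
        obs = pd.DataFrame(
            {"locus": ["a", "b"], "clone": "c1", "hap1": [30, 0], "hap2": [0, 30]}
        )
        results = _fit_table(obs)
        assert not results.nonparametric_enabled
        # calls fall back to the parametric criterion alone
        assert results.observations["called"].all()

    def test_tie_never_callable(self):
        obs, _ = simulate_aei_table(seed=5, n_null=100, n_mono=20, n_clones=2)
        obs.loc[0, ["hap1", "hap2"]] = [200, 200]
        results = _fit_table(obs)
        row = results.observations.iloc[0]
        assert row["favored"] == "none" and not row["called"]

    def test_haplotype_swap_symmetry(self):
        obs, _ = simulate_aei_table(seed=31, n_null=300, n_mono=60, n_clones=3)
        mirrored = obs.rename(columns={"hap1": "hap2", "hap2": "hap1"})
        a = _fit_table(obs).observations
        b = _fit_table(mirrored).observations
        assert a["aei"].equals(b["aei"])
        assert a["p_value"].equals(b["p_value"])
        assert a["q_value"].equals(b["q_value"])
        assert a["called"].equals(b["called"])
        swap = {"hap1": "hap2", "hap2": "hap1", "none": "none"}
        assert b["favored"].tolist() == [swap[f] for f in a["favored"]]
        state_swap = {MONO_HAP1: MONO_HAP2, MONO_HAP2: MONO_HAP1}
        assert b["state"].tolist() == [state_swap.get(s, s) for s in a["state"]]

    def test_bh_families_are_separate_per_kind(self):
        obs, _ = simulate_aei_table(seed=8, n_null=100, n_mono=10, n_clones=2, kind="TL")
        coding, _ = simulate_aei_table(seed=9, n_null=100, n_mono=10, n_clones=2, kind="coding")
        coding["locus"] = "G" + coding["locus"]
        both = pd.concat([obs, coding], ignore_index=True)
        combined = _fit_table(both).observations
        alone = _fit_table(obs).observations
        merged = combined[combined["kind"] == "TL"].merge(
            alone, on=["locus", "clone"], suffixes=("_joint", "_alone")
        )
        assert merged["q_value_joint"].to_numpy() == pytest.approx(
            merged["q_value_alone"].to_numpy(), nan_ok=True
        )


class TestXSkewControl:
    def _results(self, seed=41, flip_clone=None):
        obs, _ = simulate_aei_table(
            seed=seed, n_null=30, n_mono=40, n_clones=3, opposite_fraction=0.0
        )
        # restrict planted mono loci to one orientation to mimic the X
        mono = obs["locus"].isin([f"L{i}" for i in range(31, 71)])
        h = obs.loc[mono, ["hap1", "hap2"]].max(axis=1)
        low = obs.loc[mono, ["hap1", "hap2"]].min(axis=1)
        obs.loc[mono, "hap1"] = h
        obs.loc[mono, "hap2"] = low
        if flip_clone:
            sel = mono & (obs["clone"] == flip_clone)
            obs.loc[sel, ["hap1", "hap2"]] = obs.loc[sel, ["hap2", "hap1"]].to_numpy()
        return _fit_table(obs)

    LAYOUT = GenomeLayout({"chr1": 10_000_000, "chrX": 10_000_000}, x_chromosome="chrX")

    def _chrom_map(self, obs):
        return {
            locus: ("chrX" if locus in {f"L{i}" for i in range(31, 71)} else "chr1")
            for locus in obs["locus"].unique()
        }

    def test_consistent_orientation_passes(self):
        results = self._results()
        report = results.x_skew_control(self._chrom_map(results.observations), self.LAYOUT)
        assert report.status == "pass"
        assert set(report.clone_orientation.values()) == {"hap1"}

    def test_flipped_clone_fails(self):
        results = self._results(flip_clone="clone2")
        report = results.x_skew_control(self._chrom_map(results.observations), self.LAYOUT)
        assert report.status == "fail"

    def test_no_calls_inconclusive(self):
        obs, _ = simulate_aei_table(seed=42, n_null=60, n_mono=0, n_clones=2)
        results = _fit_table(obs)
        chrom_map = {locus: "chrX" for locus in obs["locus"].unique()}
        report = results.x_skew_control(chrom_map, self.LAYOUT)
        assert report.status == "inconclusive"
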