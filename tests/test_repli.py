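"""RT profiles: binning, quantile normalization, SD_alleles outliers."""

import numpy as np
import pandas as pd
import pytest

from asarscan.io import HAP1, HAP2, UNINFORMATIVE
from asarscan.layout import GenomeLayout
from asarscan.repli import (
    ReplicationTimingModel,
    bin_repliseq,
    make_windows,
    merge_outlier_windows,
    quantile_normalize,
    rt_profile,
)

LAYOUT = GenomeLayout({"chr1": 1_000_000}, x_chromosome=None)


class TestBinning:
    def test_half_open_window_boundary(self):
        reads = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "pos": [249_999, 250_000, 0],
                "clone": "c1",
                "haplotype": [HAP1, HAP1, HAP2],
                "fraction": "early",
            }
        )
        counts = bin_repliseq(reads, LAYOUT)
        h1 = counts[(counts["haplotype"] == HAP1) & (counts["early"] > 0)]
        assert sorted(h1["start"]) == [0, 250_000]

    def test_uninformative_reads_excluded(self):
        reads = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [100, 200, 300],
                "clone": "c1",
                "haplotype": [HAP1, UNINFORMATIVE, "conflicted"],
                "fraction": "early",
            }
        )
        counts = bin_repliseq(reads, LAYOUT)
        assert counts["early"].sum() == 1

    def test_uniform_reads_spread_multinomially(self):
        rng = np.random.default_rng(0)
        n = 10_000
        reads = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": rng.integers(0, 1_000_000, n),
                "clone": "c1",
                "haplotype": HAP1,
                "fraction": "late",
            }
        )
        counts = bin_repliseq(reads, LAYOUT)
        per_window = counts[counts["haplotype"] == HAP1]["late"]
        assert len(per_window) == 4
        assert per_window.sum() == n
        assert (np.abs(per_window - 2500) <= 3 * np.sqrt(2500)).all()

    def test_bad_window_size_rejected(self):
        with pytest.raises(ValueError, match="window"):
            make_windows(LAYOUT, window=0)
        with pytest.raises(ValueError, match="window"):
            make_windows(LAYOUT, window=2.5)


class TestQuantileNormalize:
    def test_rank_mean_definition(self):
        matrix = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        normed = quantile_normalize(matrix)
        expected = [2.5, 3.5, 4.5]
        assert normed["a"].tolist() == expected
        assert normed["b"].tolist() == expected

    def test_identical_samples_fixed_point(self):
        matrix = pd.DataFrame({"a": [3.0, 1.0, 7.0], "b": [3.0, 1.0, 7.0]})
        pd.testing.assert_frame_equal(quantile_normalize(matrix), matrix)

    def test_permutation_gives_same_multiset(self):
        rng = np.random.default_rng(1)
        a = rng.random(50)
        matrix = pd.DataFrame({"a": a, "b": rng.random(50)})
        permuted = matrix.copy()
        permuted["a"] = a[::-1]
        n1 = quantile_normalize(matrix)["a"].sort_values().to_numpy()
        n2 = quantile_normalize(permuted)["a"].sort_values().to_numpy()
        assert n1 == pytest.approx(n2)

    def test_ties_share_rank_mean(self):
        matrix = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        normed = quantile_normalize(matrix)
        assert normed["a"][0] == normed["a"][1]

    def test_constant_sample_rejected(self):
        matrix = pd.DataFrame({"a": [0.0, 0.0, 0.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            quantile_normalize(matrix)


class TestRtProfile:
    def test_log_ratio(self):
        value = rt_profile(np.array([8.0]), np.array([2.0]), pseudocount=0, min_reads=1)
        assert value[0] == pytest.approx(2.0)

    def test_equal_fractions_zero(self):
        value = rt_profile(np.array([5.0]), np.array([5.0]), min_reads=1)
        assert value[0] == pytest.approx(0.0)

    def test_thin_window_masked(self):
        value = rt_profile(np.array([0.0, 4.0]), np.array([0.0, 4.0]), min_reads=10)
        assert np.isnan(value[0])
        assert np.isnan(value[1])  # 8 < 10


def _counts_from_profiles(log2_by_profile, layout, total=1000.0):
    """Deterministic counts whose log2(E/L) equals the requested values."""
    rows = []
    for (clone, hap), values in log2_by_profile.items():
        windows = make_windows(layout)
        assert len(values) == len(windows)
        for (row, m) in zip(windows.itertuples(index=False), values):
            f = 2.0**m / (1 + 2.0**m)
            rows.append(
                (row.chrom, row.start, row.end, clone, hap,
                 int(round(total * f)), int(round(total * (1 - f))))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "clone", "haplotype", "early", "late"]
    )


class TestSdOutliers:
    LAYOUT = GenomeLayout({"chr1": 5_000_000}, x_chromosome=None)  # 20 windows

    def test_identical_profiles_no_outliers(self):
        base = np.linspace(-1, 1, 20)
        profiles = {
            (f"c{i}", hap): base for i in range(3) for hap in (HAP1, HAP2)
        }
        counts = _counts_from_profiles(profiles, self.LAYOUT)
        results = ReplicationTimingModel(counts, self.LAYOUT).fit()
        assert results.sd["combined"].max() < 1e-9
        assert not results.outliers["combined"].any()
        assert results.vert_loci().empty

    def test_hap1_restricted_outlier_detected(self):
        # window 10: hap1 = +1.5 in 3 clones, -1.5 in 3 clones; hap2 flat
        rng = np.random.default_rng(3)
        profiles = {}
        for i in range(6):
            h1 = rng.normal(0, 0.05, 20)
            h2 = rng.normal(0, 0.05, 20)
            h1[10] = 1.5 if i < 3 else -1.5
            profiles[(f"c{i}", HAP1)] = h1
            profiles[(f"c{i}", HAP2)] = h2
        counts = _counts_from_profiles(profiles, self.LAYOUT)
        results = ReplicationTimingModel(
            counts, self.LAYOUT, quantile_normalization=None
        ).fit()
        flags = results.outliers["hap1"]
        assert flags[10]
        assert flags.sum() == 1
        # direct SD oracle on the constructed table
        vals = np.array([1.5, 1.5, 1.5, -1.5, -1.5, -1.5])
        assert results.sd["hap1"].iloc[10] == pytest.approx(vals.std(ddof=1), rel=0.1)
        assert not results.outliers["hap2"][10]

    def test_k_zero_flags_everything_above_center(self):
        rng = np.random.default_rng(5)
        profiles = {
            (f"c{i}", hap): rng.normal(0, 0.2, 20)
            for i in range(3) for hap in (HAP1, HAP2)
        }
        counts = _counts_from_profiles(profiles, self.LAYOUT)
        model = ReplicationTimingModel(counts, self.LAYOUT, quantile_normalization=None)
        strict = model.fit(k=2.5)
        loose = model.fit(k=0.0)
        assert loose.outliers["combined"].sum() >= strict.outliers["combined"].sum()
        center = strict.sd["combined"].mean()
        expected = (strict.sd["combined"] >= center).sum()
        assert loose.outliers["combined"].sum() == expected

    def test_fewer_than_two_profiles_all_masked(self):
        profiles = {("c0", HAP1): np.linspace(-1, 1, 20)}
        counts = _counts_from_profiles(profiles, self.LAYOUT)
        results = ReplicationTimingModel(
            counts, self.LAYOUT, quantile_normalization=None
        ).fit(scopes=("hap1",))
        assert results.sd["hap1"].isna().all()
        assert not results.outliers["hap1"].any()

    def test_scale_invariance_of_profiles(self):
        rng = np.random.default_rng(8)
        profiles = {
            (f"c{i}", hap): rng.normal(0, 0.5, 20)
            for i in range(2) for hap in (HAP1, HAP2)
        }
        counts = _counts_from_profiles(profiles, self.LAYOUT, total=10_000)
        scaled = counts.copy()
        scaled[["early", "late"]] = scaled[["early", "late"]] * 7
        a = ReplicationTimingModel(counts, self.LAYOUT, pseudocount=0).profiles()
        b = ReplicationTimingModel(scaled, self.LAYOUT, pseudocount=0).profiles()
        pd.testing.assert_frame_equal(a, b)

    def test_clone_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        profiles = {
            (f"c{i}", hap): rng.normal(0, 0.3, 20)
            for i in range(3) for hap in (HAP1, HAP2)
        }
        counts = _counts_from_profiles(profiles, self.LAYOUT)
        relabel = {"c0": "c2", "c1": "c0", "c2": "c1"}
        permuted = counts.assign(clone=counts["clone"].map(relabel))
        a = ReplicationTimingModel(counts, self.LAYOUT).fit()
        b = ReplicationTimingModel(permuted, self.LAYOUT).fit()
        pd.testing.assert_series_equal(a.sd["combined"], b.sd["combined"])


class TestMergeOutlierWindows:
    WINDOWS = make_windows(GenomeLayout({"chr1": 2_500_000}))  # 10 windows

    def test_adjacent_windows_merge(self):
        flags = np.zeros(10, dtype=bool)
        flags[[0, 1]] = True
        loci = merge_outlier_windows(self.WINDOWS, flags)
        assert loci[["start", "end", "n_windows"]].values.tolist() == [[0, 500_000, 2]]

    def test_gap_breaks_locus_at_default_join(self):
        flags = np.zeros(10, dtype=bool)
        flags[[0, 3]] = True  # two non-outlier windows between
        loci = merge_outlier_windows(self.WINDOWS, flags, max_join=1)
        assert len(loci) == 2

    def test_larger_join_bridges_gap(self):
        flags = np.zeros(10, dtype=bool)
        flags[[0, 3]] = True
        loci = merge_outlier_windows(self.WINDOWS, flags, max_join=3)
        assert len(loci) == 1
        assert loci.iloc[0]["end"] == 1_000_000

    def test_no_outliers_empty(self):
        loci = merge_outlier_windows(self.WINDOWS, np.zeros(10, dtype=bool))
        assert loci.empty


class TestEndToEndRecovery:
    def test_planted_vert_recovered_on_demo(self, demo_dataset):
        cfg = demo_dataset.config
        results = ReplicationTimingModel(demo_dataset.repliseq, cfg.layout).fit()
        vert = results.vert_loci()
        truth = demo_dataset.truth.rt_loci
        for row in truth.itertuples(index=False):
            hits = vert[
                (vert["chrom"] == row.chrom)
                & (vert["start"] < row.end)
                & (vert["end"] > row.start)
            ]
            assert len(hits) >= 1, f"planted RT locus {row.locus} not recovered"
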