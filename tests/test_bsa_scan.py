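import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkmap import (
    FilterConfig,
    ScanConfig,
    ThresholdConfig,
    call_regions,
    compute_index,
    filter_variants,
    null_threshold,
    region_size_mb,
    window_scan,
)
from bulkmap.bsa_scan import WindowProfile, run_scan, window_centers


def make_table(rows):
    """rows: (pos, p1, p2, a_ref, a_alt, b_ref, b_alt)"""
    return pd.DataFrame(
        [("A01", *r[:1], "SNP", *r[1:]) for r in rows],
        columns=[
            "chrom",
            "pos",
            "variant_type",
            "parent1_gt",
            "parent2_gt",
            "bulkA_ref_depth",
            "bulkA_alt_depth",
            "bulkB_ref_depth",
            "bulkB_alt_depth",
        ],
    )


def make_track(pos, delta, depth=20):
    """IndexTrack-shaped frame with the requested deltas."""
    delta = np.asarray(delta, dtype=float)
    return pd.DataFrame(
        {
            "chrom": "A01",
            "pos": np.asarray(pos),
            "variant_type": "SNP",
            "index_A": (1 + delta) / 2,
            "index_B": (1 - delta) / 2,
            "delta": delta,
            "depth_A": depth,
            "depth_B": depth,
        }
    )


class TestFilterVariants:
    def test_deep_informative_site_retained(self):
        table = make_table([(100, "0/0", "1/1", 3, 3, 3, 3)])
        out = filter_variants(table, FilterConfig())
        assert len(out) == 1

    def test_depth_bound_is_strict(self):
        # one bulk total depth exactly 5 -> removed ("> 5x" read literally)
        table = make_table([(100, "0/0", "1/1", 3, 2, 3, 3)])
        out = filter_variants(table, FilterConfig(min_depth=5))
        assert out.empty

    def test_uninformative_parents_removed(self):
        table = make_table([(100, "0/0", "0/0", 5, 5, 5, 5)])
        assert filter_variants(table, FilterConfig()).empty

    def test_heterozygous_parent_removed(self):
        table = make_table([(100, "0/1", "1/1", 5, 5, 5, 5)])
        assert filter_variants(table, FilterConfig()).empty

    def test_parent_filter_can_be_disabled(self):
        table = make_table([(100, "0/0", "0/0", 5, 5, 5, 5)])
        cfg = FilterConfig(require_parent_informative=False)
        assert len(filter_variants(table, cfg)) == 1

    def test_empty_result_ok(self):
        table = make_table([(100, "0/0", "1/1", 1, 1, 1, 1)])
        assert filter_variants(table, FilterConfig()).empty


class TestComputeIndex:
    def test_all_ref(self):
        track = compute_index(make_table([(100, "1/1", "0/0", 10, 0, 10, 0)]))
        assert track.loc[0, "index_A"] == 0.0

    def test_all_alt(self):
        track = compute_index(make_table([(100, "1/1", "0/0", 0, 10, 0, 10)]))
        assert track.loc[0, "index_A"] == 1.0

    def test_recessive_expectation_delta(self):
        # head bulk fixed (index 1), non-head at the F2 conditional 1/3
        track = compute_index(make_table([(100, "1/1", "0/0", 0, 30, 20, 10)]))
        assert track.loc[0, "delta"] == pytest.approx(2 / 3)

    def test_zero_depth_asserts(self):
        table = make_table([(100, "1/1", "0/0", 0, 0, 5, 5)])
        with pytest.raises(AssertionError):
            compute_index(table)

    def test_bounds(self, small_variant_table):
        track = compute_index(small_variant_table)
        assert track["index_A"].between(0, 1).all()
        assert track["delta"].between(-1, 1).all()


class TestWindowScan:
    def test_single_variant_window_mean(self):
        track = make_track([50_000], [0.4])
        cfg = ScanConfig(min_variants_per_window=1)
        profile = window_scan(track, cfg, {"A01": 100_000})
        frame = profile.frames["A01"]
        hit = frame[frame["n_variants"] > 0]
        assert np.allclose(hit["mean_delta"], 0.4)

    def test_two_variant_mean(self):
        track = make_track([49_000, 51_000], [0.2, 0.4])
        cfg = ScanConfig(min_variants_per_window=1)
        profile = window_scan(track, cfg, {"A01": 100_000})
        frame = profile.frames["A01"]
        both = frame[frame["n_variants"] == 2]
        assert np.allclose(both["mean_delta"], 0.3)

    def test_loess_reproduces_constant(self):
        pos = np.arange(1, 201) * 5_000
        track = make_track(pos, np.full(len(pos), 0.5))
        profile = window_scan(track, ScanConfig(), {"A01": 1_000_000})
        frame = profile.frames["A01"]
        ok = frame["smoothed_delta"].dropna()
        assert np.allclose(ok, 0.5, atol=1e-6)

    def test_sparse_windows_missing_not_zero(self):
        track = make_track([500_000], [0.4])
        profile = window_scan(track, ScanConfig(), {"A01": 1_000_000})
        frame = profile.frames["A01"]
        assert frame["mean_delta"].isna().all()  # 1 variant < default 3

    def test_row_order_invariance(self, small_variant_table):
        cfg = ScanConfig(window_size=200_000, step=50_000, min_variants_per_window=1)
        track = compute_index(filter_variants(small_variant_table, FilterConfig()))
        shuffled = compute_index(
            filter_variants(
                small_variant_table.sample(frac=1.0, random_state=1), FilterConfig()
            )
        )
        a = window_scan(track, cfg, {"A01": 1_000_000}).frames["A01"]
        b = window_scan(shuffled, cfg, {"A01": 1_000_000}).frames["A01"]
        pd.testing.assert_frame_equal(a, b)


def enumeration_threshold(depth, confidence):
    """Exact confidence quantile of |X/d - Y/d|, X,Y ~ Binomial(d, 1/2),
    by exhaustive enumeration of the (d+1) x (d+1) outcome grid."""
    pmf = stats.binom.pmf(np.arange(depth + 1), depth, 0.5)
    values = {}
    for a, b in itertools.product(range(depth + 1), repeat=2):
        v = abs(a - b) / depth
        values[v] = values.get(v, 0.0) + pmf[a] * pmf[b]
    support = sorted(values)
    cdf = 0.0
    for v in support:
        cdf += values[v]
        if cdf >= confidence:
            return v
    return support[-1]


class TestNullThreshold:
    @staticmethod
    def _one_variant_per_window(depth, null_reps=10_000, seed=0):
        # windows of 10 kb stepping 10 kb, one variant each
        pos = np.arange(1, 21) * 10_000 - 5_000
        track = make_track(pos, np.zeros(len(pos)), depth=depth)
        scan_cfg = ScanConfig(window_size=10_000, step=10_000,
                              min_variants_per_window=1)
        thr_cfg = ThresholdConfig(null_reps=null_reps, seed=seed)
        return null_threshold(track, scan_cfg, thr_cfg, {"A01": 200_000})["A01"]

    def test_matches_exact_enumeration_depth10(self):
        # depth 10 is a boundary case (exact cdf just below the quantile
        # is 0.98818); 10^5 replicates keep the order statistic safe
        oracle = enumeration_threshold(10, 0.99)
        thr = self._one_variant_per_window(10, null_reps=100_000)
        raw = thr["threshold_raw"].dropna()
        assert np.allclose(raw, oracle, atol=0.02)

    @pytest.mark.parametrize("depth", [4, 8, 12])
    def test_matches_exact_enumeration_other_depths(self, depth):
        oracle = enumeration_threshold(depth, 0.99)
        thr = self._one_variant_per_window(depth)
        raw = thr["threshold_raw"].dropna()
        assert np.allclose(raw, oracle, atol=0.02)

    def test_threshold_vanishes_at_high_depth(self):
        thr = self._one_variant_per_window(100_000, null_reps=2000)
        assert (thr["threshold"].dropna() < 0.01).all()

    def test_non_increasing_in_depth(self):
        lo = self._one_variant_per_window(10, null_reps=5000, seed=1)
        hi = self._one_variant_per_window(100, null_reps=5000, seed=1)
        assert (hi["threshold"].dropna().to_numpy()
                <= lo["threshold"].dropna().to_numpy()).all()

    def test_deterministic_given_seed(self):
        a = self._one_variant_per_window(10, null_reps=500, seed=3)
        b = self._one_variant_per_window(10, null_reps=500, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCallRegions:
    @staticmethod
    def _profile(smoothed, thresholds, window_size=100_000, step=10_000):
        centers = (np.arange(len(smoothed)) * step + window_size // 2).astype(np.int64)
        profile = WindowProfile(window_size=window_size, step=step)
        profile.frames["A01"] = pd.DataFrame(
            {
                "center": centers,
                "n_variants": np.where(np.isnan(smoothed), 0, 5),
                "mean_delta": smoothed,
                "smoothed_delta": smoothed,
            }
        )
        thr = {
            "A01": pd.DataFrame(
                {"center": centers, "threshold_raw": thresholds, "threshold": thresholds}
            )
        }
        return profile, thr

    def test_no_regions_below_threshold(self):
        smoothed = np.full(30, 0.1)
        profile, thr = self._profile(smoothed, np.full(30, 0.3))
        assert call_regions(profile, thr).empty

    def test_single_run(self):
        smoothed = np.full(30, 0.1)
        smoothed[10:15] = 0.5
        profile, thr = self._profile(smoothed, np.full(30, 0.3))
        regions = call_regions(profile, thr)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r.start == 10 * 10_000  # first window's left edge
        assert r.end == 14 * 10_000 + 100_000
        assert r.sign == 1

    def test_negative_peak_called_with_sign(self):
        smoothed = np.full(30, -0.1)
        smoothed[5:9] = -0.6
        profile, thr = self._profile(smoothed, np.full(30, 0.3))
        regions = call_regions(profile, thr)
        assert len(regions) == 1
        assert regions.iloc[0].sign == -1

    def test_merge_across_single_missing_window(self):
        smoothed = np.full(30, 0.5)
        smoothed[15] = np.nan  # missing, not sub-threshold
        profile, thr = self._profile(smoothed, np.full(30, 0.3))
        assert len(call_regions(profile, thr)) == 1

    def test_no_merge_across_two_missing_windows(self):
        smoothed = np.full(30, 0.5)
        smoothed[14:16] = np.nan
        profile, thr = self._profile(smoothed, np.full(30, 0.3))
        assert len(call_regions(profile, thr)) == 2

    def test_no_merge_across_subthreshold_window(self):
        smoothed = np.full(30, 0.5)
        smoothed[15] = 0.1  # valid but below threshold
        profile, thr = self._profile(smoothed, np.full(30, 0.3))
        assert len(call_regions(profile, thr)) == 2

    def test_grid_mismatch_raises(self):
        profile, thr = self._profile(np.full(10, 0.5), np.full(10, 0.3))
        thr["A01"] = thr["A01"].iloc[:5]
        with pytest.raises(ValueError, match="grids"):
            call_regions(profile, thr)


class TestRegionSize:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (18137278, 21860151, 3.72),
            (134474, 596970, 0.46),
            (10696712, 10796712, 0.1),
            (34693040, 35853039, 1.16),
        ],
    )
    def test_reported_sizes(self, start, end, expected):
        assert region_size_mb(start, end) == expected


class TestRunScan:
    def test_snp_indel_scanned_separately(self, small_variant_table):
        result = run_scan(
            small_variant_table,
            scan_cfg=ScanConfig(window_size=500_000, step=100_000,
                                min_variants_per_window=1),
            thr_cfg=ThresholdConfig(null_reps=200, seed=0),
            chrom_lengths={"A01": 1_000_000},
        )
        assert set(result.profiles) == {"SNP-index", "indel-index"}

    def test_window_centers_cover_chromosome(self):
        cfg = ScanConfig(window_size=100_000, step=10_000)
        centers = window_centers(1_000_000, cfg)
        assert centers[0] == 50_000
        assert centers[-1] == 950_000
        assert np.all(np.diff(centers) == 10_000)


class TestPlot:
    def test_plot_smoke(self, small_variant_table, tmp_path):
        from bulkmap.bsa_scan import plot_scan

        cfg = ScanConfig(window_size=200_000, step=50_000, min_variants_per_window=1)
        track = compute_index(filter_variants(small_variant_table, FilterConfig()))
        profile = window_scan(track, cfg, {"A01": 1_000_000})
        thr = null_threshold(track, cfg, ThresholdConfig(null_reps=200, seed=0),
                             {"A01": 1_000_000})
        out = tmp_path / "scan.png"
        plot_scan(track, profile, thr, str(out))
        assert out.stat().st_size > 0
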