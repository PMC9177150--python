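import itertools

import numpy as np
import pytest
from scipy import stats

from stereomer import brainshift as bs
from stereomer.exceptions import InsufficientOverlapError
from stereomer.models import DepthProfile, ShiftEstimate


def profile(values, top=10.0):
    values = np.asarray(values, float)
    grid = top - 0.1 * np.arange(len(values))
    return DepthProfile(grid, values)


def boxcar(n=141, top=10.0, lo=-1.0, hi=3.0, inside=2.0, outside=1.0):
    grid = top - 0.1 * np.arange(n)
    vals = np.where((grid >= lo) & (grid <= hi), inside, outside)
    return DepthProfile(grid, vals.astype(float))


class TestAtanTransform:
    def test_values_and_missing_preserved(self):
        p = profile([0.0, 10.0, np.nan])
        out = bs.atan_transform(p)
        assert out.values[0] == 0.0
        assert out.values[1] == pytest.approx(np.arctan(10.0))
        assert out.values[1] < np.pi / 2
        assert np.isnan(out.values[2])

    def test_monotone(self, rng):
        x = np.sort(rng.normal(0, 3, 50))
        out = bs.atan_transform(profile(x))
        assert np.all(np.diff(out.values) > 0)


class TestXcorrMaxLag:
    def test_identical_profiles_give_zero_lag_unit_correlation(self, rng):
        p = profile(rng.normal(0, 1, 141))
        est = bs.xcorr_max_lag(p, p)
        assert est.lag_mm == 0.0
        assert est.max_xcorr == pytest.approx(1.0, abs=1e-12)

    def test_exact_on_grid_shift_recovered(self, rng):
        vals = rng.normal(0, 1, 141)
        ephys = profile(vals, top=10.0)
        # anatomy carries the same pattern 1.0 mm lower: physiological
        # pattern sits 1.0 mm above it -> lag +1.0
        anatomy = profile(vals, top=9.0)
        est = bs.xcorr_max_lag(ephys, anatomy)
        assert est.lag_mm == pytest.approx(1.0)
        assert est.max_xcorr == pytest.approx(1.0, abs=1e-12)

    def test_shift_equivariance_on_grid(self, rng):
        vals = rng.normal(0, 1, 141)
        ephys = profile(vals)
        base = bs.xcorr_max_lag(ephys, profile(vals)).lag_mm
        for k in (-7, 3, 12):
            shifted_anatomy = profile(vals, top=10.0 - 0.1 * k)
            est = bs.xcorr_max_lag(ephys, shifted_anatomy)
            assert est.lag_mm == pytest.approx(base + 0.1 * k, abs=1e-9)
            shifted_ephys = profile(vals, top=10.0 + 0.1 * k)
            est2 = bs.xcorr_max_lag(shifted_ephys, profile(vals))
            assert est2.lag_mm == pytest.approx(base + 0.1 * k, abs=1e-9)

    def test_noisy_boxcar_shift_recovered(self):
        # nucleus signature sits 0.7 mm above the imaging one, noise at SNR 5
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            anatomy = boxcar()
            ephys = boxcar(lo=-1.0 + 0.7, hi=3.0 + 0.7)
            ephys = DepthProfile(ephys.dtt_mm,
                                 ephys.values + rng.normal(0, 0.2, 141))
            est = bs.xcorr_max_lag(ephys, anatomy)
            errs.append(abs(est.lag_mm - 0.7))
        assert np.median(errs) <= 0.2

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.normal(0, 1, 141)
        e, a = profile(vals + rng.normal(0, 0.3, 141)), profile(vals)
        ref = bs.xcorr_max_lag(e, a)
        scaled = bs.xcorr_max_lag(
            DepthProfile(e.dtt_mm, 5.0 * e.values - 3.0),
            DepthProfile(a.dtt_mm, 2.0 * a.values + 11.0))
        assert scaled.lag_mm == ref.lag_mm
        assert scaled.max_xcorr == pytest.approx(ref.max_xcorr, abs=1e-9)

    def test_insufficient_overlap_is_error(self, rng):
        short = profile(rng.normal(0, 1, 25))
        with pytest.raises(InsufficientOverlapError):
            bs.xcorr_max_lag(short, short, max_lag_mm=2.0)


def estimates(lags, xcorrs=None, imaging=None):
    n = len(lags)
    xcorrs = xcorrs if xcorrs is not None else np.linspace(0.9, 0.1, n)
    imaging = imaging if imaging is not None else np.zeros(n)
    return [ShiftEstimate(f"t{i}", float(xcorrs[i]), float(lags[i]), float(imaging[i]))
            for i in range(n)]


class TestLagGroups:
    def test_single_outlier_forms_high_group(self):
        # 16 trajectories; the better-correlating half has lags {0 x7, 5}
        lags = [0, 0, 0, 0, 0, 0, 0, 5] + [1] * 8
        groups = bs.split_lag_groups(estimates(lags))
        assert [s.lag_mm for s in groups.high] == [5.0]
        assert len(groups.low) == 1 and groups.low[0].lag_mm == 0.0

    def test_equal_lags_are_degenerate(self):
        groups = bs.split_lag_groups(estimates([1.0] * 8))
        assert groups.degenerate and not groups.high and not groups.low

    def test_groups_always_equal_size(self, rng):
        for _ in range(20):
            lags = rng.normal(0, 1, int(rng.integers(6, 30)))
            groups = bs.split_lag_groups(estimates(lags))
            assert len(groups.low) == len(groups.high)


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        with pytest.warns(UserWarning):
            _, p = bs.compare_shift_groups([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_extreme_separation_matches_exhaustive_permutation_oracle(self):
        x, y = [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]
        stat, p = bs.compare_shift_groups(x, y)
        # exhaustive rank-sum null: all C(6,3)=20 group assignments
        pooled = np.array(x + y)
        ranks = stats.rankdata(pooled)
        observed = ranks[:3].sum()
        null = [sum(c) for c in itertools.combinations(ranks, 3)]
        extreme = np.mean([abs(s - 10.5) >= abs(observed - 10.5) for s in null])
        assert p == pytest.approx(extreme, abs=1e-12)

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        reps = 2000
        x = rng.normal(0, 1, (30, reps))
        y = rng.normal(0, 1, (30, reps))
        p = stats.mannwhitneyu(x, y, alternative="two-sided", axis=0).pvalue
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_signed_rank_variant_available(self):
        stat, p = bs.compare_shift_groups([1, 2, 3, 4.0], [2, 3, 4, 6.0],
                                          method="signed-rank")
        assert 0 <= p <= 1


class TestLagImagingCorrelation:
    def test_perfect_correlations(self):
        ests = estimates([1, 2, 3, 4.0], imaging=[1, 2, 3, 4.0])
        r, _ = bs.correlate_lag_with_imaging(ests)
        assert r == pytest.approx(1.0)
        ests = estimates([1, 2, 3, 4.0], imaging=[-1, -2, -3, -4.0])
        r, _ = bs.correlate_lag_with_imaging(ests)
        assert r == pytest.approx(-1.0)

    def test_known_population_correlation_recovered(self, rng):
        n, rho = 500, 0.5
        x = rng.normal(0, 1, n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        ests = estimates(x, imaging=y)
        r, _ = bs.correlate_lag_with_imaging(ests)
        assert r == pytest.approx(rho, abs=0.1)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            bs.correlate_lag_with_imaging(estimates([1.0, 1.0, 1.0]))


class TestFDR:
    def test_bh_matches_brute_force(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = float(rng.choice([0.01, 0.05, 0.1]))
            got = bs.bh_fdr(p, q)
            # brute force: largest k with p_(k) <= k q / m, reject the k smallest
            order = np.argsort(p)
            ks = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * q / m))
            expected = np.zeros(m, bool)
            if len(ks):
                expected[order[: ks.max() + 1]] = True
            np.testing.assert_array_equal(got, expected)


class TestDepthBandComparison:
    def test_identical_constant_profiles_have_no_significant_bins(self):
        profiles = [profile(np.ones(60)) for _ in range(20)]
        res = bs.depth_band_comparison(profiles, np.arange(20, dtype=float))
        assert not res.bins["significant"].any()
        assert res.band_mm is None

    def test_shifted_band_is_detected_with_controlled_false_positives(self):
        hit = miss = null_flag = null_total = 0
        band = (6.0, 8.0)  # dtt window where near-nucleus profiles are elevated
        for seed in range(100):
            rng = np.random.default_rng(seed)
            profiles, dist = [], []
            for i in range(40):
                base = rng.normal(0, 0.5, 60)
                near = i < 20
                if near:
                    grid = 10.0 - 0.1 * np.arange(60)
                    base = base + 2.0 * ((grid >= band[0]) & (grid <= band[1]))
                profiles.append(profile(base))
                dist.append(0.0 if near else 10.0)
            res = bs.depth_band_comparison(profiles, np.asarray(dist), frac=0.5)
            for _, row in res.bins.iterrows():
                in_band = band[0] <= row["dtt_mm"] <= band[1]
                if in_band:
                    hit += bool(row["significant"])
                    miss += not row["significant"]
                else:
                    null_flag += bool(row["significant"])
                    null_total += 1
        assert hit / (hit + miss) >= 0.90
        assert null_flag / null_total <= 0.01

    def test_null_fdr_is_controlled(self):
        flagged = total = 0
        for seed in range(300):
            rng = np.random.default_rng(seed)
            profiles = [profile(rng.normal(0, 1, 30)) for _ in range(30)]
            res = bs.depth_band_comparison(profiles, np.arange(30, dtype=float))
            flagged += int(res.bins["significant"].sum())
            total += len(res.bins)
        assert flagged / total <= 0.01

    def test_median_entry_exit_of_near_group_reported(self):
        profiles = [profile(np.ones(60)) for _ in range(10)]
        ee = [(float(2 + i), float(-1 - i)) for i in range(10)]
        res = bs.depth_band_comparison(profiles, np.arange(10, dtype=float),
                                       entry_exit_mm=ee)
        # nearest 20% = trajectories 0 and 1
        assert res.median_entry_exit_mm == (2.5, -1.5)
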