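import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bcikit.eeg_core import Epoch
from bcikit.mi_features import (
    FEATURE_NAMES,
    FeatureConfig,
    approximate_entropy,
    apply_normalizer,
    ar_coefficients,
    band_power_welch,
    featurize_epoch,
    featurize_epochs,
    fit_normalizer,
    fractal_dimension,
    higher_order_stats,
    hjorth,
    permutation_entropy,
    sample_entropy,
)

from oracles import apen_brute, hos_brute, permen_brute, sampen_brute, simulate_ar


class TestBandPower:
    def test_zero_signal_zero_power(self):
        assert band_power_welch(np.zeros(500), 250.0, (8, 12)) == 0.0

    def test_mu_sinusoid_concentrates_in_mu_band(self):
        t = np.arange(0, 4, 1 / 250)
        x = np.sin(2 * np.pi * 10 * t)
        mu = band_power_welch(x, 250.0, (8, 12))
        beta = band_power_welch(x, 250.0, (13, 30))
        assert mu > 50 * beta

    def test_white_noise_total_power_matches_variance(self, rng):
        x = rng.normal(size=8000)
        total = band_power_welch(x, 250.0, (0.5, 124.0))
        assert total == pytest.approx(np.var(x), rel=0.10)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power_welch(np.ones(500), 250.0, (100, 130))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            band_power_welch(np.ones(100), 250.0, (8, 12))

    def test_power_scales_quadratically(self, rng):
        x = rng.normal(size=2000)
        p1 = band_power_welch(x, 250.0, (8, 12))
        p3 = band_power_welch(3 * x, 250.0, (8, 12))
        assert p3 == pytest.approx(9 * p1, rel=1e-9)


class TestHjorth:
    def test_constant_signal_degenerates(self):
        with pytest.warns(UserWarning):
            act, mob, comp = hjorth(np.full(100, 2.5))
        assert act == 0.0 and math.isnan(mob) and math.isnan(comp)

    def test_sinusoid_mobility_matches_difference_oracle(self):
        fs, f = 1000.0, 5.0
        x = np.sin(2 * np.pi * f * np.arange(5000) / fs)
        act, mob, comp = hjorth(x)
        # independent direct computation from variances of differences
        d1, d2 = np.diff(x), np.diff(np.diff(x))
        mob_oracle = math.sqrt(np.var(d1, ddof=1) / np.var(x, ddof=1))
        comp_oracle = math.sqrt(np.var(d2, ddof=1) / np.var(d1, ddof=1)) / mob_oracle
        assert mob == pytest.approx(mob_oracle, abs=1e-9)
        assert comp == pytest.approx(comp_oracle, abs=1e-9)
        # densely sampled sinusoid: per-sample mobility ~ 2*pi*f/fs
        assert mob == pytest.approx(2 * np.pi * f / fs, rel=0.01)
        assert comp == pytest.approx(1.0, rel=0.01)

    def test_activity_is_sample_variance(self, rng):
        x = rng.normal(size=300)
        act, _, _ = hjorth(x)
        assert act == pytest.approx(np.var(x, ddof=1), rel=1e-12)

    @given(scale=st.floats(0.1, 50), offset=st.floats(-10, 10))
    def test_mobility_complexity_affine_invariant(self, scale, offset):
        x = np.random.default_rng(7).normal(size=200)
        _, mob, comp = hjorth(x)
        _, mob2, comp2 = hjorth(scale * x + offset)
        assert mob2 == pytest.approx(mob, rel=1e-9)
        assert comp2 == pytest.approx(comp, rel=1e-9)


class TestAR:
    PHI = np.array([0.5, -0.3, 0.2, -0.1])

    def test_recovers_ar4_parameters(self):
        x = simulate_ar(self.PHI, 10_000, seed=42)
        est = ar_coefficients(x, 4)
        np.testing.assert_allclose(est, self.PHI, atol=0.05)

    def test_white_noise_has_near_zero_coefficients(self, rng):
        est = ar_coefficients(rng.normal(size=10_000), 4)
        assert np.all(np.abs(est) < 0.05)

    def test_ar1_fit_at_order_4(self):
        x = simulate_ar([0.9], 20_000, seed=3)
        est = ar_coefficients(x, 4)
        assert est[0] == pytest.approx(0.9, abs=0.05)
        assert np.all(np.abs(est[1:]) < 0.1)

    def test_bias_shrinks_with_n(self):
        errs = []
        for n in (500, 5_000, 50_000):
            x = simulate_ar(self.PHI, n, seed=11)
            errs.append(np.abs(ar_coefficients(x, 4) - self.PHI).max())
        assert errs[2] < errs[0]

    def test_burg_agrees_with_statsmodels(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        x = simulate_ar(self.PHI, 4_000, seed=5)
        mine = ar_coefficients(x, 4, method="burg")
        ref, _sigma2 = sm_burg(x - x.mean(), order=4, demean=False)
        np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_yule_walker_route_close_to_burg(self):
        x = simulate_ar(self.PHI, 20_000, seed=9)
        np.testing.assert_allclose(
            ar_coefficients(x, 4, "burg"), ar_coefficients(x, 4, "yule_walker"), atol=0.02
        )

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.ones(100), 4)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.arange(12.0), 4)


class TestFractalDimension:
    def test_straight_line_has_dimension_one(self):
        assert fractal_dimension(np.arange(500.0), 10) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_approaches_two(self, rng):
        fd = fractal_dimension(rng.normal(size=5000), 10)
        assert fd == pytest.approx(2.0, abs=0.15)

    def test_sinusoid_closer_to_one(self):
        x = np.sin(2 * np.pi * 2 * np.arange(2000) / 250.0)
        fd = fractal_dimension(x, 10)
        assert abs(fd - 1.0) < abs(fd - 2.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.ones(50), 10)


class TestEntropies:
    def test_constant_signal_apen_zero(self):
        assert approximate_entropy(np.full(40, 3.0), 2, 0.5) == pytest.approx(0.0)

    def test_constant_signal_sampen_zero(self):
        assert sample_entropy(np.full(40, 3.0), 2, 0.5) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [20, 35, 50])
    def test_apen_matches_brute_force(self, n, rng):
        x = rng.normal(size=n)
        r = 0.2 * x.std()
        assert approximate_entropy(x, 2, r) == pytest.approx(
            apen_brute(x, 2, r), abs=1e-10
        )

    @pytest.mark.parametrize("n", [20, 35, 50])
    def test_sampen_matches_brute_force(self, n, rng):
        x = rng.normal(size=n)
        r = 0.25 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(
            sampen_brute(x, 2, r), abs=1e-10
        )

    def test_periodic_less_entropic_than_shuffled(self, rng):
        periodic = np.array([0.0, 1.0] * 25)
        shuffled = periodic.copy()
        rng.shuffle(shuffled)
        r = 0.3
        assert apen_brute(periodic, 2, r) == pytest.approx(
            approximate_entropy(periodic, 2, r), abs=1e-10
        )
        assert approximate_entropy(periodic, 2, r) < approximate_entropy(shuffled, 2, r)

    def test_noise_sampen_exceeds_sinusoid_at_matched_variance(self, rng):
        n = 400
        noise = rng.normal(size=n)
        sine = np.sin(2 * np.pi * 5 * np.arange(n) / 250.0)
        sine *= noise.std() / sine.std()
        r = 0.2 * noise.std()
        assert sample_entropy(noise, 2, r) > sample_entropy(sine, 2, r)

    def test_sampen_no_matches_gives_inf(self):
        x = np.array([0.0, 10.0, -10.0, 20.0, -20.0, 40.0])
        with pytest.warns(UserWarning):
            assert sample_entropy(x, 2, 1e-6) == math.inf


class TestPermutationEntropy:
    def test_monotonic_sequence_zero(self):
        assert permutation_entropy(np.arange(50.0), 3, 1) == 0.0

    def test_uniform_noise_near_log_m_factorial(self, rng):
        h = permutation_entropy(rng.uniform(size=10_000), 3, 1)
        assert h == pytest.approx(math.log(6), rel=0.02)

    @pytest.mark.parametrize("m,delay", [(2, 1), (3, 1), (3, 2)])
    def test_matches_brute_force_histogram(self, m, delay, rng):
        x = rng.normal(size=20)
        assert permutation_entropy(x, m, delay) == pytest.approx(
            permen_brute(x, m, delay), abs=1e-12
        )

    def test_ties_follow_order_of_appearance(self):
        x = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        assert permutation_entropy(x, 3, 1) == pytest.approx(
            permen_brute(x, 3, 1), abs=1e-12
        )

    @given(scale=st.floats(0.5, 20), offset=st.floats(-5, 5))
    def test_affine_invariance(self, scale, offset):
        x = np.random.default_rng(3).normal(size=100)
        assert permutation_entropy(scale * x + offset, 3, 1) == pytest.approx(
            permutation_entropy(x, 3, 1), abs=1e-12
        )

    def test_normalized_variant_at_most_one(self, rng):
        h = permutation_entropy(rng.normal(size=500), 3, 1, normalized=True)
        assert 0.0 <= h <= 1.0


class TestHigherOrderStats:
    def test_symmetric_two_point_closed_form(self):
        skew, kurt, var, sd = higher_order_stats(np.array([-1.0, 1.0]))
        assert skew == pytest.approx(0.0)
        assert kurt == pytest.approx(-2.0)
        assert var == pytest.approx(2.0)
        assert sd == pytest.approx(math.sqrt(2.0))

    def test_large_gaussian_sample_near_zero_moments(self, rng):
        x = rng.normal(size=100_000)
        skew, kurt, _, _ = higher_order_stats(x)
        assert abs(skew) < 0.05 and abs(kurt) < 0.05

    @pytest.mark.parametrize("n", [5, 17, 50])
    def test_matches_literal_formula_oracle(self, n, rng):
        x = rng.normal(size=n) * 3 + 1
        got = higher_order_stats(x)
        expected = hos_brute(x)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_zero_spread_gives_nan_sentinels(self):
        with pytest.warns(UserWarning):
            skew, kurt, var, sd = higher_order_stats(np.full(10, 4.0))
        assert math.isnan(skew) and math.isnan(kurt)
        assert var == 0.0 and sd == 0.0


class TestFeaturizeEpoch:
    def make_epoch(self, n_ch, n_s=750, fs=250.0, rng=None):
        rng = rng or np.random.default_rng(0)
        return Epoch(
            data=rng.normal(size=(n_ch, n_s)),
            fs=fs,
            label="REST",
            t_start=0.0,
            t_end=n_s / fs,
            channel_labels=[f"c{i}" for i in range(n_ch)],
        )

    def test_vector_length_is_channels_times_17(self):
        assert len(FEATURE_NAMES) == 17
        fv = featurize_epoch(self.make_epoch(3))
        assert fv.values.shape == (3 * 17,)
        assert fv.layout[:17] == [("c0", name) for name in FEATURE_NAMES]

    def test_deterministic_on_identical_epochs(self):
        a = featurize_epoch(self.make_epoch(2))
        b = featurize_epoch(self.make_epoch(2))
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_epochs_all_finite(self, rng):
        for _ in range(10):
            fv = featurize_epoch(self.make_epoch(2, rng=rng))
            assert np.all(np.isfinite(fv.values))
            assert not fv.flagged

    def test_constant_channel_flags_epoch(self):
        ep = self.make_epoch(2)
        ep.data[1] = 5.0
        fv = featurize_epoch(ep)
        assert fv.flagged
        assert np.isnan(fv.values[17 + FEATURE_NAMES.index("mobility")])

    def test_matrix_assembly_marks_flagged_rows(self):
        good, bad = self.make_epoch(1), self.make_epoch(1)
        bad.data[0] = 1.0
        X, labels, layout, flagged = featurize_epochs([good, bad])
        assert X.shape == (2, 17)
        assert flagged.tolist() == [False, True]


class TestNormalizer:
    def test_training_matrix_standardized(self, rng):
        X = rng.normal(5, 3, size=(40, 6))
        params = fit_normalizer(X)
        Z = apply_normalizer(X, params)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_passes_through_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            params = fit_normalizer(X)
        Z = apply_normalizer(X, params)
        np.testing.assert_allclose(Z[:, 1], 0.0, atol=1e-12)

    def test_test_vectors_use_training_parameters_only(self, rng):
        X_train = rng.normal(0, 1, size=(30, 4))
        X_test = rng.normal(10, 1, size=(30, 4))
        params = fit_normalizer(X_train)
        Z = apply_normalizer(X_test, params)
        own_z = (X_test - X_test.mean(axis=0)) / X_test.std(axis=0)
        assert not np.allclose(Z, own_z)
        assert Z.mean() > 5  # shifted mean survives: train params were used

    def test_layout_mismatch_rejected(self, rng):
        params = fit_normalizer(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            apply_normalizer(np.zeros(5), params)
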