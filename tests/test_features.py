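import numpy as np
import pandas as pd
import pytest
import pywt

from respibreath.errors import StratificationError
from respibreath.features import (
    FAMILY_NAMES,
    FeatureConfig,
    compute_feature_vector,
    compute_scalar_feature,
    first_derivative,
    sample_entropy,
    select_features,
)

from .oracles import (
    count_prominent_peaks,
    dft_coefficient,
    ratio_beyond_sigma_naive,
    sample_entropy_naive,
)

CFG = FeatureConfig()


class TestFirstDerivative:
    def test_first_difference(self):
        np.testing.assert_array_equal(first_derivative([1.0, 3.0, 6.0]), [2.0, 3.0])

    def test_constant_and_ramp(self):
        np.testing.assert_array_equal(first_derivative(np.full(5, 2.0)), np.zeros(4))
        np.testing.assert_allclose(first_derivative(0.7 * np.arange(6)), np.full(5, 0.7))

    def test_too_short(self):
        with pytest.raises(ValueError):
            first_derivative([1.0])


class TestScalarFamilies:
    def test_count_above_mean(self):
        assert compute_scalar_feature("count_above_mean", [1, 2, 3, 4], CFG)["n"] == 2

    def test_number_crossings(self):
        out = compute_scalar_feature("number_crossings", [1, -1, 1, -1], CFG)
        assert out["m_0"] == 3

    def test_crossings_ignore_exact_zeros(self):
        out = compute_scalar_feature("number_crossings", [1, 0, 1, -1], CFG)
        assert out["m_0"] == 1

    def test_energy_ratio_uniform_for_constant_series(self):
        out = compute_scalar_feature(
            "energy_ratio_by_chunks", np.full(300, 3.0), CFG
        )
        np.testing.assert_allclose(list(out.values()), 0.1)

    def test_energy_ratios_sum_to_one(self):
        x = np.random.default_rng(0).normal(size=301)
        out = compute_scalar_feature("energy_ratio_by_chunks", x, CFG)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_skewness_zero_for_symmetric_sample(self):
        x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        assert compute_scalar_feature("skewness", x, CFG)["g1"] == pytest.approx(0.0)

    def test_count_partition(self):
        x = np.random.default_rng(3).integers(0, 5, 40).astype(float)
        above = compute_scalar_feature("count_above_mean", x, CFG)["n"]
        below = compute_scalar_feature("count_below_mean", x, CFG)["n"]
        equal = np.sum(x == x.mean())
        assert above + below + equal == len(x)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            compute_scalar_feature("autocorrelation", np.arange(10.0), CFG)

    def test_degenerate_inputs_impute_to_nan(self):
        x = np.zeros(300)
        assert np.isnan(compute_scalar_feature("skewness", x, CFG)["g1"])
        assert np.isnan(compute_scalar_feature("sample_entropy", x, CFG)["m_2"])
        assert np.isnan(compute_scalar_feature("adf", x, CFG)["stat"])


class TestOracleEquivalence:
    def test_sample_entropy_matches_naive_template_count(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=300)
        assert sample_entropy(x) == pytest.approx(sample_entropy_naive(x), rel=1e-12)

    def test_sample_entropy_many_series(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(50, 200)
            x = np.cumsum(rng.normal(size=n))
            got = sample_entropy(x)
            want = sample_entropy_naive(x)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)

    def test_fourier_pure_tone_concentrates(self):
        n, k = 300, 7
        x = np.sin(2 * np.pi * k * np.arange(n) / n)
        out = compute_scalar_feature("fourier_coefficients", x, CFG)
        mags = {j: np.hypot(out[f"real_{j}"], out[f"imag_{j}"]) for j in range(10)}
        assert all(mags[j] < 1e-9 * mags[k] for j in mags if j != k)

    def test_fourier_matches_dft_definition(self):
        x = np.random.default_rng(1).normal(size=128)
        out = compute_scalar_feature("fourier_coefficients", x, CFG)
        for k in range(10):
            want = dft_coefficient(x, k)
            assert out[f"real_{k}"] == pytest.approx(want.real, abs=1e-8)
            assert out[f"imag_{k}"] == pytest.approx(want.imag, abs=1e-8)

    def test_ratio_beyond_sigma_matches_naive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_t(df=3, size=rng.integers(20, 300))
            out = compute_scalar_feature("ratio_beyond_r_sigma", x, CFG)
            for r in (1.0, 2.0):
                assert out[f"r_{r:g}"] == pytest.approx(ratio_beyond_sigma_naive(x, r))

    def test_cwt_peak_count_matches_walkout_count(self):
        """Peak counting on the Mexican-hat transform rows equals an
        exhaustive prominence walk-out count at the same threshold."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = np.cumsum(rng.normal(size=300))
            coeffs, _ = pywt.cwt(x, CFG.cwt_widths, "mexh")
            want = sum(
                count_prominent_peaks(row, CFG.cwt_rel_prominence * (row.max() - row.min()))
                for row in coeffs
                if row.max() > row.min()
            )
            got = compute_scalar_feature("cwt_peaks", x, CFG)["n"]
            assert got == want


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [0.5, 3.0, 100.0])
    def test_invariant_families(self, scale):
        x = np.random.default_rng(11).normal(size=300)
        for family in ("number_crossings", "symmetry_looking", "sample_entropy"):
            base = compute_scalar_feature(family, x, CFG)
            scaled = compute_scalar_feature(family, scale * x, CFG)
            for key in base:
                assert scaled[key] == pytest.approx(base[key], rel=1e-9)


class TestFeatureVector:
    def test_shape_contract(self, tiny_events, tiny_resistance):
        v0 = compute_feature_vector(tiny_events[0], tiny_resistance)
        v1 = compute_feature_vector(tiny_events[1], tiny_resistance)
        assert list(v0) == list(v1)
        per_family_arity = 2 + 1 + 1 + 1 + 10 + 1 + 1 + 1 + 1 + 20 + 3 + 1 + 5
        assert len(v0) == 6 * per_family_arity

    def test_determinism(self, tiny_events, tiny_resistance):
        a = compute_feature_vector(tiny_events[0], tiny_resistance)
        b = compute_feature_vector(tiny_events[0], tiny_resistance)
        assert a == b

    def test_channel_independence(self, tiny_events, tiny_resistance):
        import copy

        event = tiny_events[0]
        base = compute_feature_vector(event, tiny_resistance)
        scaled_rec = copy.deepcopy(tiny_resistance)
        scaled_rec.channels["abdomen"] = scaled_rec.channels["abdomen"] * 2.0
        scaled = compute_feature_vector(event, scaled_rec)
        for name in base:
            if name.startswith(("upper_chest.", "lower_chest.")):
                assert scaled[name] == base[name]
        changed = [n for n in base if n.startswith("abdomen.")
                   and scaled[n] != base[n]]
        assert changed  # scale-sensitive abdomen features did move

    def test_window_outside_recording(self, tiny_resistance, tiny_events):
        from dataclasses import replace

        bad = replace(tiny_events[0], window_end=tiny_resistance.n_samples + 10)
        with pytest.raises(ValueError):
            compute_feature_vector(bad, tiny_resistance)

    def test_all_families_present_in_names(self, tiny_matrix):
        for family in FAMILY_NAMES:
            assert any(family in c for c in tiny_matrix.columns)


class TestSelectFeatures:
    def _synthetic(self, n=80, p=100, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"f{i:03d}" for i in range(p)]
        )
        X["f000"] = y + 0.01 * rng.normal(size=n)
        return X, y

    def test_top_fraction_count(self):
        X, y = self._synthetic()
        selected = select_features(X, y, n_folds=5, top_fraction=0.10, seed=0)
        assert len(selected) == 10

    def test_informative_feature_ranked_first(self):
        X, y = self._synthetic()
        selected = select_features(X, y, n_folds=5, top_fraction=0.10, seed=0)
        assert selected[0] == "f000"

    def test_seeded_determinism(self):
        X, y = self._synthetic()
        a = select_features(X, y, n_folds=5, seed=3)
        b = select_features(X, y, n_folds=5, seed=3)
        assert a == b

    def test_single_class_rejected(self):
        X, _ = self._synthetic()
        with pytest.raises(StratificationError):
            select_features(X, np.zeros(len(X), dtype=int), n_folds=5)
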