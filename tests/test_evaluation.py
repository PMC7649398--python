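import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutrex import (
    SampleSizeSpec,
    effective_sample_size,
    effective_sample_size_raw,
    evaluate,
    mse_decomposition,
    sample_size_curve,
)


def oracle_shares(pred, act):
    """Closed-form decomposition oracle with population moments."""
    p, a = np.asarray(pred, float), np.asarray(act, float)
    sp, sa = p.std(), a.std()
    r = np.corrcoef(p, a)[0, 1] if sp > 0 and sa > 0 else 0.0
    bias = (p.mean() - a.mean()) ** 2
    slope = (sp - r * sa) ** 2
    random = (1 - r ** 2) * sa ** 2
    tot = bias + slope + random
    return bias / tot, slope / tot, random / tot


class TestEvaluate:
    def test_hand_arithmetic_example(self):
        m = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.mae == pytest.approx(2 / 3)
        assert m.rmse == pytest.approx(math.sqrt(2 / 3))
        assert m.mae_rel == pytest.approx((2 / 3) / 2)

    def test_perfect_prediction_conventions(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mae == 0 and m.rmse == 0
        assert m.r2 == pytest.approx(1.0)
        assert (m.mse_bias_share, m.mse_slope_share, m.mse_random_share) == (0, 0, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0, 2.0])

    def test_regression_slope_and_intercept_reported(self):
        rng = np.random.default_rng(0)
        act = rng.uniform(50, 150, 100)
        pred = 5 + 0.9 * act + rng.normal(0, 5, 100)
        m = evaluate(pred, act)
        assert m.slope == pytest.approx(0.9, abs=0.05)
        assert m.intercept == pytest.approx(5, abs=6)
        assert 0 <= m.r2 <= 1
        assert m.p_slope_vs_1 < 0.05  # slope clearly differs from unity here

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40),
           st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_rmse_dominates_mae(self, act, seed):
        rng = np.random.default_rng(seed)
        act = np.asarray(act)
        pred = act + rng.normal(0, 10, act.size)
        m = evaluate(pred, act)
        assert m.rmse >= m.mae - 1e-12


class TestMseDecomposition:
    def test_pure_translation_is_all_bias(self):
        act = np.array([1.0, 2.0, 3.0, 4.0])
        bias, slope, random = mse_decomposition(act + 5.0, act)
        assert bias == pytest.approx(1.0)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert random == pytest.approx(0.0, abs=1e-12)

    def test_pure_scaling_of_zero_mean_data_is_all_slope(self):
        act = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        bias, slope, random = mse_decomposition(2.0 * act, act)
        assert slope == pytest.approx(1.0)

    def test_matches_closed_form_oracle_on_degenerate_actual(self):
        pred, act = [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]
        assert mse_decomposition(pred, act) == pytest.approx(
            oracle_shares(pred, act))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_shares_sum_to_one_and_reconstruct_mse(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 60)
        act = rng.normal(100, 20, n)
        pred = rng.normal(0.5, 0.5) + rng.normal(1.0, 0.3) * act \
            + rng.normal(0, 10, n)
        shares = mse_decomposition(pred, act)
        assert sum(shares) == pytest.approx(1.0, abs=1e-9)
        assert min(shares) >= 0
        # the three un-normalised terms rebuild the MSE exactly
        mse = np.mean((np.asarray(act) - np.asarray(pred)) ** 2)
        assert np.allclose(np.array(shares) * mse,
                           np.array(oracle_shares(pred, act)) * mse)


#: SD consistent with a design that needs 68 direct-measurement animals
#: to resolve a 10 g/animal/d difference at alpha 0.05 (one-tailed), beta 0.20
SIGMA_68 = 23.45


class TestEffectiveSampleSize:
    def spec(self, **kw):
        defaults = dict(alpha=0.05, beta=0.20, sigma=SIGMA_68, reliability=1.0)
        defaults.update(kw)
        return SampleSizeSpec(**defaults)

    def test_direct_measurement_design(self):
        assert effective_sample_size(self.spec(), delta=10.0) == 68

    def test_model_reliability_inflates_n(self):
        n = effective_sample_size(self.spec(reliability=0.63), delta=10.0)
        assert n == 108  # 67.996 / 0.63 = 107.9, whole animals

    def test_halved_reliability_doubles_raw_n(self):
        full = effective_sample_size_raw(self.spec(), 10.0)
        half = effective_sample_size_raw(self.spec(reliability=0.5), 10.0)
        assert half == pytest.approx(2 * full, rel=1e-12)

    def test_invariant_to_joint_rescaling(self):
        a = effective_sample_size_raw(self.spec(sigma=20.0), 8.0)
        b = effective_sample_size_raw(self.spec(sigma=60.0), 24.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_decreasing_in_delta(self):
        ns = [effective_sample_size(self.spec(), d) for d in range(1, 31)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))
        assert ns[0] > ns[-1]

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(self.spec(), 0.0)

    def test_t_quantiles_require_more_animals_than_z(self):
        z = effective_sample_size(self.spec(), 10.0)
        t = effective_sample_size(self.spec(), 10.0, quantiles="t")
        assert t > z

    def test_bad_quantile_family_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(self.spec(), 10.0, quantiles="cauchy")


class TestSampleSizeCurve:
    def test_composes_with_pointwise_sizes(self):
        spec = SampleSizeSpec(sigma=SIGMA_68, reliability=0.63,
                              delta_grid=(10.0,))
        curve = sample_size_curve(spec)
        assert len(curve) == 1
        assert curve.n_actual.iloc[0] == 68
        assert curve.n_predicted.iloc[0] == 108

    def test_strictly_decreasing_over_printed_grid(self):
        spec = SampleSizeSpec(sigma=SIGMA_68, reliability=0.63)
        curve = sample_size_curve(spec)
        assert len(curve) == 30
        assert (curve.n_actual.diff().dropna() <= 0).all()
        assert (curve.n_predicted >= curve.n_actual).all()

    def test_models_converge_for_large_differences(self):
        # beyond ~20 g/d the two designs need similarly few animals: the
        # gap shrinks to a small fraction of its value at 10 g/d
        spec = SampleSizeSpec(sigma=SIGMA_68, reliability=0.63)
        curve = sample_size_curve(spec).set_index("delta")
        gap = curve.n_predicted - curve.n_actual
        assert gap.loc[10.0] == 108 - 68
        assert (gap.loc[20.0:] <= gap.loc[10.0] / 3).all()

    def test_error_free_model_needs_no_extra_animals(self):
        spec = SampleSizeSpec(sigma=SIGMA_68, reliability=1.0)
        curve = sample_size_curve(spec)
        assert (curve.n_predicted == curve.n_actual).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sample_size_curve(SampleSizeSpec(sigma=SIGMA_68, delta_grid=()))
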