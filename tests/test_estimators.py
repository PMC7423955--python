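import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fepkit.constants import kt
from fepkit.estimators import (
    accumulate,
    bar,
    estimate_window,
    statistical_inefficiency,
    subsample,
    zwanzig,
)
from fepkit.synthetic import WindowSamples


def brute_force_bar(w_f, w_r, temperature, grid_half_width=5.0):
    """Independent oracle: locate the Bennett root by grid scan.

    Evaluates the self-consistent equation's residual on a dG grid and
    brackets the sign change, refining the grid twice before a final
    linear interpolation. No root-finder library involved.
    """
    w_f = np.asarray(w_f, float)
    w_r = np.asarray(w_r, float)
    beta = 1.0 / kt(temperature)
    M = math.log(w_f.size / w_r.size)

    def residual(grid):
        lhs = np.sum(1.0 / (1.0 + np.exp(M + beta * (w_f[None, :] - grid[:, None]))), axis=1)
        rhs = np.sum(1.0 / (1.0 + np.exp(-M + beta * (w_r[None, :] + grid[:, None]))), axis=1)
        return lhs - rhs

    center = 0.5 * (np.mean(w_f) - np.mean(w_r))
    lo, hi = center - grid_half_width, center + grid_half_width
    for _ in range(3):  # three refinement passes: width 10 -> ~1e-8
        grid = np.linspace(lo, hi, 2001)
        res = residual(grid)
        i = np.where(np.diff(np.sign(res)) != 0)[0][0]
        lo, hi = grid[i], grid[i + 1]
    y0, y1 = residual(np.array([lo, hi]))
    return lo - y0 * (hi - lo) / (y1 - y0)


class TestZwanzig:
    def test_constant_work_is_exact(self):
        est = zwanzig([1.7, 1.7, 1.7], 300.0)
        assert est.value == pytest.approx(1.7)
        assert est.stderr == 0.0

    def test_zero_work(self):
        assert zwanzig([0.0, 0.0, 0.0], 300.0).value == 0.0

    def test_gaussian_closed_form(self, rng):
        """For Normal(mu, sigma) work, dG = mu - sigma^2 / (2 kT)."""
        mu, sigma, T, n = 2.0, 1.0, 300.0, 100_000
        w = rng.normal(mu, sigma, n)
        est = zwanzig(w, T)
        expected = mu - sigma**2 / (2.0 * kt(T))
        assert expected == pytest.approx(1.1613, abs=1e-4)
        assert abs(est.value - expected) < 3.0 * est.stderr

    def test_overflow_safe_for_large_work(self):
        est = zwanzig([5000.0, 6000.0, 7000.0], 300.0)
        assert math.isfinite(est.value)
        # exponential averaging is dominated by the smallest work value
        assert est.value == pytest.approx(5000.0, abs=1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            zwanzig([], 300.0)


class TestBar:
    def test_symmetric_constant_work(self):
        """forward all = c, reverse all = -c solves the Bennett equation at c."""
        est = bar([2.5] * 20, [-2.5] * 20, 300.0)
        assert est.value == pytest.approx(2.5, abs=1e-8)
        assert est.stderr == 0.0

    def test_matches_brute_force_grid_oracle(self, rng):
        w_f = rng.normal(1.0, 0.8, 400)
        w_r = rng.normal(-0.7, 0.8, 400)
        est = bar(w_f, w_r, 300.0)
        oracle = brute_force_bar(w_f, w_r, 300.0)
        assert est.value == pytest.approx(oracle, abs=2e-5)

    def test_swapping_directions_negates(self, rng):
        w_f = rng.normal(0.8, 0.5, 300)
        w_r = rng.normal(-0.5, 0.5, 300)
        a = bar(w_f, w_r, 300.0)
        b = bar(w_r, w_f, 300.0)
        assert a.value == pytest.approx(-b.value, abs=1e-7)

    def test_estimate_lies_between_zwanzig_bounds(self, toy_windows):
        # the sandwich between the two one-sided estimators is an
        # asymptotic property; allow one standard error of slack
        for w in toy_windows:
            est = bar(w.forward_dU, w.reverse_dU, w.temperature)
            lo_est = zwanzig(w.forward_dU, w.temperature).value
            hi_est = -zwanzig(w.reverse_dU, w.temperature).value
            lo, hi = min(lo_est, hi_est), max(lo_est, hi_est)
            assert lo - est.stderr <= est.value <= hi + est.stderr

    @given(shift=st.floats(min_value=-5.0, max_value=5.0))
    @settings(derandomize=True, max_examples=20)
    def test_shift_covariance(self, shift):
        """Adding c to forward works and subtracting c from reverse works
        moves the estimate by exactly c."""
        rng = np.random.default_rng(99)
        w_f = rng.normal(0.5, 0.6, 200)
        w_r = rng.normal(-0.3, 0.6, 200)
        base = bar(w_f, w_r, 300.0)
        shifted = bar(w_f + shift, w_r - shift, 300.0)
        assert shifted.value == pytest.approx(base.value + shift, abs=1e-6)
        assert shifted.stderr == pytest.approx(base.stderr, rel=1e-6)

    def test_disjoint_distributions_raise(self):
        with pytest.raises(ValueError, match="overlap|no root"):
            bar([1000.0, 1001.0], [1000.0, 1001.0], 300.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            bar([], [1.0], 300.0)


class TestStatisticalInefficiency:
    def test_white_noise_is_near_one(self, rng):
        g = statistical_inefficiency(rng.normal(size=10_000)).g
        assert g == pytest.approx(1.0, abs=0.2)

    def test_ar1_closed_form(self, rng):
        """AR(1) with coefficient rho has g = (1+rho)/(1-rho) = 19 at rho=0.9."""
        rho, n = 0.9, 100_000
        eps = rng.normal(size=n) * math.sqrt(1 - rho**2)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        g = statistical_inefficiency(x).g
        assert g == pytest.approx(19.0, rel=0.2)

    def test_retained_index_spacing_is_ceil_g(self, rng):
        res = statistical_inefficiency(np.repeat(rng.normal(size=50), 4))
        stride = math.ceil(res.g)
        assert np.all(np.diff(res.retained_indices) == stride)
        assert res.retained_indices[0] == 0

    def test_constant_series_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="constant"):
            res = statistical_inefficiency(np.ones(40))
        assert res.g == 40.0

    def test_identity_when_g_is_one(self, rng):
        x = rng.normal(size=5_000)
        thinned, res = subsample(x)
        if math.ceil(res.g) == 1:
            assert np.array_equal(thinned, x)


class TestEstimateWindow:
    def test_null_window_is_zero_with_zero_error(self):
        w = WindowSamples(0.0, 1.0, np.zeros(100), np.zeros(100))
        est = estimate_window(w)
        assert est.value == 0.0
        assert est.stderr == 0.0

    def test_decorrelation_is_benign_on_iid_data(self, rng):
        w = WindowSamples(
            0.0, 0.5, rng.normal(0.5, 0.4, 4_000), rng.normal(-0.3, 0.4, 4_000)
        )
        on = estimate_window(w, decorrelate=True)
        off = estimate_window(w, decorrelate=False)
        assert abs(on.value - off.value) < 3.0 * math.hypot(on.stderr, off.stderr)

    def test_delegates_to_bar(self, toy_windows):
        w = toy_windows[0]
        direct = bar(w.forward_dU, w.reverse_dU, w.temperature)
        via = estimate_window(w, method="bar", decorrelate=False)
        assert via.value == pytest.approx(direct.value, abs=1e-12)

    def test_records_effective_counts(self, toy_windows):
        est = estimate_window(toy_windows[0], decorrelate=True)
        assert est.n_effective_forward >= 1
        assert est.n_effective_reverse >= 1
        assert est.n_effective_forward <= toy_windows[0].forward_dU.size


class TestAccumulate:
    def test_three_four_five_uncertainty(self):
        from fepkit.estimators import FreeEnergyEstimate

        a = FreeEnergyEstimate(1.0, 0.3, "bar")
        b = FreeEnergyEstimate(2.0, 0.4, "bar")
        tot = accumulate([a, b])
        assert tot.value == pytest.approx(3.0)
        assert tot.stderr == pytest.approx(0.5)

    def test_single_window_unchanged(self):
        from fepkit.estimators import FreeEnergyEstimate

        e = FreeEnergyEstimate(0.7, 0.1, "bar")
        tot = accumulate([e])
        assert (tot.value, tot.stderr) == (0.7, 0.1)

    def test_permutation_invariant(self, rng):
        from fepkit.estimators import FreeEnergyEstimate

        ests = [
            FreeEnergyEstimate(v, s, "bar")
            for v, s in zip(rng.normal(size=8), rng.uniform(0.1, 1.0, 8))
        ]
        perm = [ests[i] for i in rng.permutation(8)]
        assert accumulate(ests).stderr == pytest.approx(accumulate(perm).stderr)
        assert accumulate(ests).value == pytest.approx(accumulate(perm).value)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])
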