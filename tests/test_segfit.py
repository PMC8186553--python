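"""Core numerics: segmented fitting, finite differences, level crossing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aehydro.exceptions import InvalidInputError, InvalidWindowError, OutOfRangeError
from aehydro.segfit import (
    BinnedSeries,
    SegmentedFit,
    crossing,
    finite_derivative,
    fit_segmented,
)

# --------------------------------------------------------------------------
# independent oracle: naive exhaustive grid search with per-candidate lstsq
# --------------------------------------------------------------------------


def _oracle_sse(x, y, breakpoints):
    cols = [np.ones_like(x), x] + [np.clip(x - b, 0, None) for b in breakpoints]
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def grid_oracle(x, y, n_breakpoints, min_pts=3):
    """Brute-force minimum SSE over all admissible midpoint combinations."""
    import itertools

    xs = np.sort(x)
    distinct = np.unique(xs)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    best = np.inf
    for combo in itertools.combinations(mids, n_breakpoints):
        edges = (-np.inf, *combo, np.inf)
        counts = [
            np.count_nonzero((xs > lo) & (xs <= hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        if min(counts) < min_pts:
            continue
        best = min(best, _oracle_sse(x, y, combo))
    return best


def piecewise(x, bps, intercept, slopes):
    y = intercept + slopes[0] * x
    for b, s0, s1 in zip(bps, slopes[:-1], slopes[1:]):
        y = y + (s1 - s0) * np.clip(x - b, 0, None)
    return y


class TestFitSegmented:
    def test_noiseless_single_breakpoint_recovered_exactly(self):
        x = np.arange(0.0, 11.0)
        y = np.where(x <= 5, x, 5 + 3 * (x - 5))
        fit = fit_segmented(x, y, 1)
        assert fit.breakpoints[0] == pytest.approx(5.0, abs=1e-6)
        assert fit.slopes == pytest.approx((1.0, 3.0), abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_zero_breakpoints_is_ordinary_least_squares(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 40)
        y = 1.5 * x - 0.3 + rng.normal(0, 0.2, 40)
        fit = fit_segmented(x, y, 0)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.slopes[0] == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_noisy_breakpoint_at_least_as_good_as_grid_oracle(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 60)
        y = piecewise(x, [5.0], 0.0, [1.0, 3.0]) + rng.normal(0, 0.1, 60)
        fit = fit_segmented(x, y, 1)
        assert fit.sse <= grid_oracle(x, y, 1) * (1 + 1e-6)
        # breakpoint near the grid optimum (within one grid step of truth)
        assert abs(fit.breakpoints[0] - 5.0) < 0.5

    @pytest.mark.parametrize("n_bp", [1, 2])
    def test_random_instances_match_grid_oracle(self, n_bp):
        rng = np.random.default_rng(42 + n_bp)
        for _ in range(8):
            n = rng.integers(30, 80)
            bps = np.sort(rng.uniform(2, 8, n_bp))
            if n_bp == 2 and bps[1] - bps[0] < 1.0:
                bps[1] = bps[0] + 1.0
            x = np.sort(rng.uniform(0, 10, n))
            slopes = rng.uniform(-3, 3, n_bp + 1)
            y = piecewise(x, bps, rng.uniform(-1, 1), slopes)
            y += rng.normal(0, 0.2, n)
            fit = fit_segmented(x, y, n_bp)
            assert fit.sse <= grid_oracle(x, y, n_bp) * (1 + 1e-6)

    def test_segmented_sse_never_above_ols_sse(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = np.sort(rng.uniform(0, 1, 50))
            y = rng.normal(0, 1, 50)
            assert fit_segmented(x, y, 1).sse <= fit_segmented(x, y, 0).sse + 1e-9

    def test_breakpoints_strictly_inside_range_and_increasing(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(-1, 1, 60))
        y = np.abs(x) + rng.normal(0, 0.05, 60)
        fit = fit_segmented(x, y, 2)
        assert x.min() < fit.breakpoints[0] < fit.breakpoints[1] < x.max()

    def test_insufficient_data_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_segmented([0, 1, 2], [0, 1, 2], 1)
        with pytest.raises(InvalidInputError):
            fit_segmented(np.ones(20), np.arange(20), 1)  # all x equal
        with pytest.raises(InvalidInputError):
            fit_segmented(np.arange(5), np.arange(4), 0)  # length mismatch

    def test_predict_is_continuous_at_breakpoints(self):
        fit = SegmentedFit((2.0,), 1.0, (0.5, -1.0), 0.0, 10)
        eps = 1e-9
        assert fit.predict(2.0 - eps) == pytest.approx(fit.predict(2.0 + eps), abs=1e-6)


class TestFiniteDerivative:
    def test_linear_input_gives_constant_first_derivative(self):
        series = BinnedSeries(0.0, 300.0, 10.0 / 3600.0 * 300.0 * np.arange(50))
        d1 = finite_derivative(series, 900.0, 1)
        assert d1.values * 3600 == pytest.approx(np.full(50, 10.0))

    def test_constant_series_has_zero_third_derivative(self):
        series = BinnedSeries(0.0, 300.0, np.full(40, 7.0))
        assert finite_derivative(series, 1500.0, 3).values == pytest.approx(
            np.zeros(40)
        )

    def test_logistic_first_derivative_peaks_at_midpoint(self):
        t0, tau = 6 * 3600.0, 3600.0
        t = 300.0 * np.arange(200)
        series = BinnedSeries(0.0, 300.0, 1 / (1 + np.exp(-(t - t0) / tau)))
        d1 = finite_derivative(series, 900.0, 1)
        # dense numeric oracle at dt/100
        tf = np.arange(0, t[-1], 3.0)
        dense = np.gradient(1 / (1 + np.exp(-(tf - t0) / tau)), tf)
        t_peak_oracle = tf[np.argmax(dense)]
        t_peak = d1.times[np.argmax(d1.values)]
        assert abs(t_peak - t_peak_oracle) <= 300.0

    def test_linearity_of_the_operator(self):
        rng = np.random.default_rng(2)
        f = BinnedSeries(0.0, 60.0, rng.normal(size=80))
        g = BinnedSeries(0.0, 60.0, rng.normal(size=80))
        combo = BinnedSeries(0.0, 60.0, 2.5 * f.values - 1.5 * g.values)
        for order in (1, 2, 3):
            lhs = finite_derivative(combo, 240.0, order).values
            rhs = (
                2.5 * finite_derivative(f, 240.0, order).values
                - 1.5 * finite_derivative(g, 240.0, order).values
            )
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_window_and_length_validation(self):
        series = BinnedSeries(0.0, 300.0, np.arange(10.0))
        with pytest.raises(InvalidWindowError):
            finite_derivative(series, 300.0, 1)
        with pytest.raises(InvalidInputError):
            finite_derivative(BinnedSeries(0, 300.0, np.arange(3.0)), 3000.0, 1)


class TestCrossing:
    def test_published_threshold_nodes_are_hit_exactly(self):
        # polyline through the Dublet AE_12/50/100 nodes
        x = [-1.16, -1.30, -1.38]
        y = [12.0, 50.0, 100.0]
        assert crossing(x, y, 50.0) == -1.30
        assert crossing(x, y, 12.0) == -1.16

    def test_midpoint_interpolation(self):
        assert crossing([0.0, 1.0], [0.0, 100.0], 50.0) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_segment_inversion(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = np.cumsum(rng.uniform(0.1, 1.0, n))
        y = np.cumsum(rng.uniform(0.0, 1.0, n))
        levels = rng.uniform(y[0], y[-1], 10)
        for level in levels:
            got = crossing(x, y, level)
            # brute force: walk segments and invert the first one reaching level
            expected = None
            for i in range(n):
                if y[i] == level:
                    expected = x[i]
                    break
                if y[i] > level:
                    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
                    expected = x[i - 1] + frac * (x[i] - x[i - 1])
                    break
            assert expected is not None
            assert got == pytest.approx(expected, abs=1e-9)

    def test_node_inverse_consistency(self):
        x = np.array([-0.5, -1.0, -1.7, -2.2])
        y = np.array([0.0, 12.0, 60.0, 100.0])
        for xi, yi in zip(x, y):
            assert crossing(x, y, yi) == xi

    def test_out_of_range_level_rejected(self):
        with pytest.raises(OutOfRangeError):
            crossing([0, 1], [0, 100], 150.0)
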