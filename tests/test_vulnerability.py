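"""Vulnerability curves, thresholds, replicate averaging, cross-validation."""

import numpy as np
import pytest

from aehydro import simulate, vulnerability
from aehydro.exceptions import (
    AlignmentError,
    InvalidInputError,
    MissingThresholdError,
    OutOfRangeError,
)
from aehydro.psi_axis import PsiAxis
from aehydro.segfit import BinnedSeries
from aehydro.vulnerability import (
    ThresholdSet,
    VulnerabilityCurve,
    ae50_activity_regression,
    average_curves,
    build_vc,
    compare_visual_counts,
    thresholds,
)

from conftest import run_vc_pipeline


def polyline_curve(psi_nodes, plc_nodes, endpoint_h=20.0, dt=300.0):
    n = len(psi_nodes)
    return VulnerabilityCurve(
        psi=np.asarray(psi_nodes, float),
        plc=np.asarray(plc_nodes, float),
        endpoint_time=endpoint_h * 3600.0,
        psi_at_max_activity=float(psi_nodes[n // 2]),
        dt=dt,
    )


class TestBuildVc:
    def test_grid_mismatch_rejected(self):
        plc = BinnedSeries(0.0, 300.0, np.linspace(0, 100, 30))
        axis = PsiAxis(0.0, 600.0, np.linspace(-0.5, -2.5, 30))
        with pytest.raises(AlignmentError):
            build_vc(plc, axis)

    def test_short_axis_rejected(self):
        plc = BinnedSeries(0.0, 300.0, np.linspace(0, 100, 30))
        axis = PsiAxis(0.0, 300.0, np.linspace(-0.5, -2.5, 10))
        with pytest.raises(AlignmentError):
            build_vc(plc, axis)

    def test_endpoint_bin_pairs_psi_with_100(self):
        plc = BinnedSeries(0.0, 300.0, np.linspace(0, 100, 40))
        axis = PsiAxis(0.0, 300.0, np.linspace(-0.5, -2.5, 50))
        vc = build_vc(plc, axis)
        assert vc.plc[-1] == 100.0
        assert vc.psi[-1] == axis.psi[39]

    def test_synthetic_curve_tracks_generator_law(self, excalibur_experiment,
                                                  excalibur_pipeline):
        """Recovered PLC(Ψ) stays close to the generating logistic."""
        vc, _, _, _ = excalibur_pipeline
        truth = excalibur_experiment.truth
        # the method pins PLC = 100 at the detected endpoint, so compare the
        # generating logistic under the same rescaling convention
        law = simulate.plc_logistic(vc.psi, truth.p50_true, truth.slope_s)
        expected = 100.0 * law / law[-1]
        mid = (vc.plc > 10) & (vc.plc < 90)
        assert np.median(np.abs(vc.plc[mid] - expected[mid])) < 5.0


class TestThresholds:
    def test_published_polyline_yields_printed_thresholds(self):
        # Dublet column of the threshold table as polyline nodes
        vc = polyline_curve(
            [-1.00, -1.16, -1.30, -1.37, -1.38],
            [0.0, 12.0, 50.0, 88.0, 100.0],
            endpoint_h=32.02,
        )
        t = thresholds(vc)
        assert (t.ae12, t.ae50, t.ae88, t.ae100) == (-1.16, -1.30, -1.37, -1.38)
        assert t.t100 == pytest.approx(32.02)

    def test_missing_level_reported_by_name(self):
        vc = polyline_curve([-1.0, -1.2, -1.3], [0.0, 20.0, 40.0])
        with pytest.raises(MissingThresholdError) as err:
            thresholds(vc)
        assert err.value.level == 50.0

    def test_random_monotone_curve_matches_bruteforce_inversion(self):
        rng = np.random.default_rng(15)
        psi = -np.cumsum(rng.uniform(0.01, 0.1, 60)) - 0.5
        plc = np.concatenate(([0.0], np.sort(rng.uniform(0, 100, 58)), [100.0]))
        vc = polyline_curve(psi, plc)
        t = thresholds(vc)
        for level, got in ((12, t.ae12), (50, t.ae50), (88, t.ae88)):
            i = int(np.argmax(plc >= level))
            if plc[i] == level:
                expected = psi[i]
            else:
                frac = (level - plc[i - 1]) / (plc[i] - plc[i - 1])
                expected = psi[i - 1] + frac * (psi[i] - psi[i - 1])
            assert got == pytest.approx(expected, abs=1e-9)

    def test_threshold_ordering_invariant(self, excalibur_pipeline):
        _, t, _, _ = excalibur_pipeline
        assert t.ae12 >= t.ae50 >= t.ae88 >= t.ae100
        assert t.t100 > 0

    def test_disordered_thresholds_rejected(self):
        with pytest.raises(InvalidInputError):
            ThresholdSet(ae12=-2.0, ae50=-1.0, ae88=-2.5, ae100=-3.0, t100=10.0)


class TestAverageCurves:
    def test_identical_replicates_have_zero_se(self):
        vc = polyline_curve(np.linspace(-0.5, -2.0, 50),
                            np.linspace(0, 100, 50))
        avg = average_curves([vc, vc, vc])
        assert avg.plc_se == pytest.approx(np.zeros_like(avg.psi_grid))
        assert avg.se["ae50"] == 0.0

    def test_two_polylines_match_manual_average(self):
        psi = np.linspace(-0.5, -2.0, 151)
        a = polyline_curve(psi, np.linspace(0, 100, 151))
        b = polyline_curve(psi, 100 * (np.linspace(0, 1, 151) ** 2))
        avg = average_curves([a, b])
        for target in (-0.75, -1.25, -1.75):
            i = int(np.argmin(np.abs(avg.psi_grid - target)))
            g = avg.psi_grid[i]
            manual = 0.5 * (
                np.interp(g, psi[::-1], a.plc[::-1])
                + np.interp(g, psi[::-1], b.plc[::-1])
            )
            assert avg.plc_mean[i] == pytest.approx(manual, abs=1e-9)

    def test_disjoint_psi_ranges_rejected(self):
        a = polyline_curve(np.linspace(-0.5, -1.0, 30), np.linspace(0, 100, 30))
        b = polyline_curve(np.linspace(-2.0, -3.0, 30), np.linspace(0, 100, 30))
        with pytest.raises(AlignmentError):
            average_curves([a, b])

    def test_four_seeds_recover_true_p50(self):
        """Mean AE_50 over 4 virtual shoots within ±0.07 MPa of truth."""
        ae50s = []
        for seed in range(4):
            truth = simulate.calibrated_truth("Excalibur", seed=seed)
            exp = simulate.simulate_experiment(truth, 30.0)
            _, t, _, _ = run_vc_pipeline(exp)
            ae50s.append(t.ae50)
        assert np.mean(ae50s) == pytest.approx(-2.00, abs=0.07)

    def test_max_activity_psi_tracks_ae50_on_symmetric_truth(
        self, excalibur_pipeline
    ):
        vc, t, _, _ = excalibur_pipeline
        assert vc.psi_at_max_activity == pytest.approx(t.ae50, abs=0.12)


class TestRegression:
    def test_exact_fixture_law_recovered(self):
        ae50 = np.array([-1.30, -1.47, -1.62, -2.00, -1.67])
        y = 0.909 * ae50 - 0.174
        res = ae50_activity_regression(np.column_stack([ae50, y]))
        assert res.slope == pytest.approx(0.909)
        assert res.intercept == pytest.approx(-0.174)
        assert res.r2 == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(InvalidInputError):
            ae50_activity_regression([(-1.5, -1.4), (-1.5, -1.6), (-1.5, -1.5)])
        with pytest.raises(InvalidInputError):
            ae50_activity_regression([(-1.5, -1.4), (-1.6, -1.6)])

    def test_noisy_pairs_match_normal_equations(self):
        rng = np.random.default_rng(20)
        x = rng.uniform(-2.5, -1.0, 12)
        y = 0.9 * x - 0.2 + rng.normal(0, 0.05, 12)
        res = ae50_activity_regression(np.column_stack([x, y]))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], rel=1e-9)
        assert res.slope == pytest.approx(beta[1], rel=1e-9)
        ss_res = np.sum((y - X @ beta) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert res.r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)


class TestCompareVisualCounts:
    @staticmethod
    def _cum():
        values = np.concatenate(([0.0], np.cumsum(np.full(59, 5.0))))
        return BinnedSeries(0.0, 300.0, values)

    def test_counts_sampled_from_cum_have_zero_deviation(self):
        cum = self._cum()
        endpoint = 300.0 * 50
        t = np.array([3000.0, 6000.0, 12000.0, 15000.0])
        counts = np.column_stack([t, [cum.values[int(x / 300)] for x in t]])
        dmax, dmean = compare_visual_counts(counts, cum, endpoint)
        assert dmax == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_shows_up_as_mean_deviation(self):
        """Counts sitting 10 percentage points above the AE curve deviate by 10."""
        cum = self._cum()
        endpoint = 300.0 * 50
        ae_end = cum.values[50]
        t = np.array([3000.0, 6000.0, 9000.0, endpoint])
        ae_pct = np.array([100 * cum.values[int(x / 300)] / ae_end for x in t])
        # counts are AE% + 10 everywhere except the normalizing endpoint count
        counts_pct = np.concatenate([ae_pct[:-1] + 10.0, [100.0]])
        counts = np.column_stack([t, counts_pct * 7.0])  # arbitrary scale
        dmax, dmean = compare_visual_counts(counts, cum, endpoint)
        assert dmax == pytest.approx(10.0)
        assert dmean == pytest.approx(10.0 * 3 / 4)

    def test_random_monotone_counts_match_bruteforce(self):
        rng = np.random.default_rng(31)
        cum = self._cum()
        endpoint = 300.0 * 50
        t = np.sort(rng.uniform(0, endpoint, 8))
        c = np.cumsum(rng.uniform(1, 5, 8))
        dmax, dmean = compare_visual_counts(np.column_stack([t, c]), cum, endpoint)
        devs = []
        for ti, ci in zip(t, c):
            ae_pct = 100 * cum.values[int(round(ti / 300))] / cum.values[50]
            devs.append(abs(100 * ci / c[-1] - ae_pct))
        assert dmax == pytest.approx(max(devs))
        assert dmean == pytest.approx(np.mean(devs))

    def test_counts_outside_span_rejected(self):
        with pytest.raises(OutOfRangeError):
            compare_visual_counts([(1e9, 5.0)], self._cum(), 300.0 * 50)
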