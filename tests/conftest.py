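import numpy as np
import pytest

from aehydro import acoustics, psi_axis, simulate, vulnerability


@pytest.fixture(scope="session")
def excalibur_truth():
    return simulate.calibrated_truth("Excalibur", seed=11)


@pytest.fixture(scope="session")
def excalibur_experiment(excalibur_truth):
    """One standard virtual Excalibur shoot, reused across read-only tests."""
    return simulate.simulate_experiment(excalibur_truth, 30.0)


def run_vc_pipeline(exp):
    """Full in-memory acoustic pipeline on one experiment (shared helper)."""
    retained = acoustics.filter_events(exp.events)
    cum = acoustics.cumulate(retained, span_s=exp.dendro.times[-1])
    endpoint = acoustics.detect_endpoint(cum)
    plc = acoustics.to_plc(cum, endpoint)
    shrink = psi_axis.relative_shrinkage(exp.dendro)
    fit = psi_axis.fit_stress_strain(shrink, exp.psi_obs)
    axis = psi_axis.psi_timeline(fit, shrink)
    vc = vulnerability.build_vc(plc, axis)
    return vc, vulnerability.thresholds(vc), axis, endpoint


@pytest.fixture(scope="session")
def excalibur_pipeline(excalibur_experiment):
    return run_vc_pipeline(excalibur_experiment)


def dense_d3_postpeak_max(t0_h, tau_h, duration_h=30.0, step_s=3.0):
    """Dense-numeric oracle: time (s) of the post-peak third-derivative maximum.

    Differentiates the analytic logistic on a dt/100 grid; the last few
    samples are excluded from the argmax because one-sided boundary stencils
    of the triple gradient produce spurious values there.
    """
    tf = np.arange(0.0, duration_h * 3600.0, step_s)
    dense = 1.0 / (1.0 + np.exp(-(tf / 3600.0 - t0_h) / tau_h))
    d3 = np.gradient(np.gradient(np.gradient(dense, tf), tf), tf)
    peak = int(np.argmax(np.gradient(dense, tf)))
    post = d3[peak : -10]
    return float(tf[peak + int(np.argmax(post))])


def logistic_cumulative(t0_h=12.0, tau_h=1.5, total=3000.0, dt_s=300.0,
                        duration_h=30.0):
    """Analytic logistic cumulative-AE series on the standard 5-min grid."""
    t = np.arange(0.0, duration_h * 3600.0 + 1, dt_s)
    values = total / (1.0 + np.exp(-(t / 3600.0 - t0_h) / tau_h))
    values -= values[0]
    from aehydro.segfit import BinnedSeries

    return BinnedSeries(0.0, dt_s, values)
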