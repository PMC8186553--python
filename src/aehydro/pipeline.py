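"""End-to-end drivers: raw sensor files → curves, thresholds, capacitances.

Each driver is a pure function of its input files and configuration, logs
every stage with its parameters, and tags any error with the stage at which
it occurred.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import acoustics, desorption, io, psi_axis, simulate, vulnerability
from .exceptions import AEHydroError
from .segfit import SegmentedFit

__all__ = ["VCResult", "DCResult", "run_vc", "run_dc", "run_simulate"]

log = logging.getLogger("aehydro")


@contextmanager
def _stage(name: str, config: "io.ExperimentConfig"):
    log.info("stage %s (shoot %s)", name, config.shoot_id)
    try:
        yield
    except AEHydroError as exc:
        raise type(exc)(
            f"[stage {name}, shoot {config.shoot_id}] {exc}"
        ) from exc


@dataclass
class VCResult:
    curve: vulnerability.VulnerabilityCurve
    thresholds: vulnerability.ThresholdSet
    axis: psi_axis.PsiAxis
    endpoint_s: float
    stress_strain: SegmentedFit
    n_events_retained: int


@dataclass
class DCResult:
    curve: desorption.DesorptionCurve


def run_vc(config: io.ExperimentConfig, out_dir=None) -> VCResult:
    """Full acoustic vulnerability pipeline for one shoot.

    filter → cumulate → activity → endpoint → PLC → stress–strain fit →
    Ψ axis → vulnerability curve → thresholds.  When ``out_dir`` is given,
    writes ``vc_<shoot>.csv`` (psi_mpa, plc), ``psi_axis_<shoot>.csv`` and
    ``thresholds_<shoot>.json``.
    """
    with _stage("read-inputs", config):
        events = io.read_ae_events(config.ae_events)
        dendro = io.read_dendro(config.dendrometer, config.reference_diameter_mm)
        obs = io.read_psi_obs(config.psi_obs)
    with _stage("filter-events", config):
        retained = acoustics.filter_events(
            events, config.min_amplitude_dbae, config.band_khz
        )
        log.info("retained %d / %d events", len(retained), len(events))
    with _stage("cumulate", config):
        cum = acoustics.cumulate(retained, config.bin_s, span_s=dendro.times[-1])
    with _stage("detect-endpoint", config):
        endpoint_s = acoustics.detect_endpoint(
            cum, config.d3_window_s, config.activity_window_s
        )
        log.info("endpoint at %.2f h", endpoint_s / 3600.0)
    with _stage("rescale-plc", config):
        plc = acoustics.to_plc(cum, endpoint_s)
    with _stage("stress-strain", config):
        shrink = psi_axis.relative_shrinkage(dendro, config.bin_s)
        fit = psi_axis.fit_stress_strain(shrink, obs)
    with _stage("psi-axis", config):
        axis = psi_axis.psi_timeline(fit, shrink)
    with _stage("vulnerability-curve", config):
        vc = vulnerability.build_vc(plc, axis, config.activity_window_s)
        thr = vulnerability.thresholds(vc)

    result = VCResult(
        curve=vc,
        thresholds=thr,
        axis=axis,
        endpoint_s=endpoint_s,
        stress_strain=fit,
        n_events_retained=len(retained),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = config.shoot_id
        pd.DataFrame({"psi_mpa": vc.psi, "plc": vc.plc}).to_csv(
            out / f"vc_{tag}.csv", index=False, float_format="%.6g"
        )
        io.write_psi_axis(axis, out / f"psi_axis_{tag}.csv")
        payload = asdict(thr) | {
            "psi_at_max_activity": vc.psi_at_max_activity,
            "endpoint_s": endpoint_s,
            "n_events_retained": result.n_events_retained,
        }
        (out / f"thresholds_{tag}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    return result


def run_dc(
    config: io.ExperimentConfig,
    ae100: float,
    axis: psi_axis.PsiAxis | None = None,
    out_dir=None,
) -> DCResult:
    """Desorption pipeline for one gravimetric shoot.

    The Ψ(t) mapping comes from the paired acoustic shoots (``axis``,
    typically the cultivar-mean axis, time-aligned at excision); ``ae100``
    bounds the inelastic phase on its dry end.
    """
    with _stage("read-inputs", config):
        mass = io.read_mass(config.balance)
        if axis is None:
            raise AEHydroError(
                "a Ψ axis from the paired acoustic shoots is required"
            )
    with _stage("desorption-curve", config):
        psi, loss = desorption.build_dc(mass, axis)
    with _stage("dc-breakpoints", config):
        bp1, bp2 = desorption.dc_breakpoints(psi, loss, psi_floor=ae100)
    with _stage("capacitances", config):
        c_el, c_inel = desorption.capacitances(psi, loss, bp1, bp2, ae100)
    curve = desorption.DesorptionCurve(
        psi=psi, water_loss=loss, bp1=bp1, bp2=bp2, c_el=c_el, c_inel=c_inel
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = config.shoot_id
        pd.DataFrame({"psi_mpa": psi, "water_loss_g": loss}).to_csv(
            out / f"dc_{tag}.csv", index=False, float_format="%.6g"
        )
        (out / f"dc_summary_{tag}.json").write_text(
            json.dumps(
                {"bp1": bp1, "bp2": bp2, "c_el": c_el, "c_inel": c_inel,
                 "ae100": ae100},
                indent=2, sort_keys=True,
            ) + "\n"
        )
    return DCResult(curve=curve)


def run_simulate(
    config: io.ExperimentConfig, out_dir, truth: simulate.TruthParams | None = None
) -> simulate.BenchExperiment:
    """Generate a virtual experiment and write every stream as CSV.

    ``truth`` defaults to the calibration for ``config.cultivar`` with
    ``config.seed``; the truth parameters are serialized alongside so
    recovery experiments can compare against them.
    """
    if truth is None:
        truth = simulate.calibrated_truth(config.cultivar, seed=config.seed)
    exp = simulate.simulate_experiment(truth, config.duration_h)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.shoot_id
    io.write_ae_events(exp.events, out / f"ae_events_{tag}.csv")
    io.write_dendro(exp.dendro, out / f"dendro_{tag}.csv")
    io.write_mass(exp.mass, out / f"mass_{tag}.csv")
    io.write_psi_obs(exp.psi_obs, out / f"psi_obs_{tag}.csv")
    truth_data = asdict(truth)
    truth_data["shrink_slopes"] = list(truth.shrink_slopes)
    truth_data["too_short"] = exp.too_short
    with open(out / f"truth_{tag}.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth_data, fh, sort_keys=False)
    return exp
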