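"""Acoustic vulnerability curves, AE thresholds and replicate summaries.

A vulnerability curve pairs PLC (%) with the continuous Ψ_xylem axis.  The
headline statistics are the water potentials at 12, 50, 88 and 100% of
embolism-related acoustic emission (AE_12 … AE_100), the dehydration time to
full embolism (t_100%), and the Ψ at maximum acoustic activity — whose
near-unit regression on AE_50 across cultivars reflects that most embolism
forms in a narrow Ψ window around AE_50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .acoustics import DEFAULT_ACTIVITY_WINDOW_S, ae_activity
from .exceptions import (
    AlignmentError,
    InvalidInputError,
    MissingThresholdError,
    OutOfRangeError,
)
from .psi_axis import PsiAxis
from .segfit import BinnedSeries, crossing

__all__ = [
    "VulnerabilityCurve",
    "ThresholdSet",
    "AveragedCurves",
    "RegressionResult",
    "build_vc",
    "thresholds",
    "average_curves",
    "ae50_activity_regression",
    "compare_visual_counts",
]

THRESHOLD_LEVELS = (12.0, 50.0, 88.0)
DEFAULT_PSI_GRID_STEP = 0.01  # MPa, below pressure-chamber precision


@dataclass
class VulnerabilityCurve:
    """PLC (%) against Ψ_xylem (MPa) up to the detected endpoint."""

    psi: np.ndarray
    plc: np.ndarray
    endpoint_time: float  # s since excision
    psi_at_max_activity: float  # MPa
    t0: float = 0.0
    dt: float = 300.0

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.plc = np.asarray(self.plc, dtype=float)
        if self.psi.shape != self.plc.shape or self.psi.ndim != 1:
            raise InvalidInputError("psi and plc must be 1-D arrays of equal length")
        if self.plc.min() < -1e-9 or self.plc.max() > 100 + 1e-9:
            raise InvalidInputError("PLC must lie in [0, 100]")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.psi.size)


@dataclass(frozen=True)
class ThresholdSet:
    """Ψ at 12/50/88/100% embolism-related AE plus time to full embolism (h)."""

    ae12: float
    ae50: float
    ae88: float
    ae100: float
    t100: float

    def __post_init__(self):
        seq = (self.ae12, self.ae50, self.ae88, self.ae100)
        if any(a < b - 1e-9 for a, b in zip(seq[:-1], seq[1:])):
            raise InvalidInputError(
                f"thresholds must satisfy AE_12 >= AE_50 >= AE_88 >= AE_100, got {seq}"
            )
        if self.t100 <= 0:
            raise InvalidInputError("t_100% must be positive")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float


@dataclass
class AveragedCurves:
    """Replicate mean ± SE vulnerability curve and per-shoot thresholds."""

    psi_grid: np.ndarray
    plc_mean: np.ndarray
    plc_se: np.ndarray
    per_shoot: list[ThresholdSet]
    mean: ThresholdSet
    se: dict  # field name -> standard error (SEs need not obey the ordering invariant)


def build_vc(
    plc: BinnedSeries,
    axis: PsiAxis,
    activity_window_s: float = DEFAULT_ACTIVITY_WINDOW_S,
) -> VulnerabilityCurve:
    """Pair PLC with Ψ on the shared 5-min grid.

    The Ψ at maximum activity is read off the first derivative of the PLC
    series itself (PLC is rescaled cumulative AE, so its activity peak sits
    at the same bin as the raw acoustic activity peak).
    """
    if abs(plc.t0 - axis.t0) > 1e-9 or abs(plc.dt - axis.dt) > 1e-9:
        raise AlignmentError(
            f"PLC grid (t0={plc.t0}, dt={plc.dt}) does not match Ψ axis "
            f"(t0={axis.t0}, dt={axis.dt})"
        )
    if len(axis) < len(plc):
        raise AlignmentError("Ψ axis shorter than the PLC series")
    psi = axis.psi[: len(plc)]
    activity = ae_activity(plc, activity_window_s)
    peak_idx = int(np.argmax(activity.values))
    endpoint_time = plc.t0 + (len(plc) - 1) * plc.dt
    return VulnerabilityCurve(
        psi=psi,
        plc=plc.values.copy(),
        endpoint_time=endpoint_time,
        psi_at_max_activity=float(psi[peak_idx]),
        t0=plc.t0,
        dt=plc.dt,
    )


def thresholds(vc: VulnerabilityCurve) -> ThresholdSet:
    """AE_12/50/88 by first level crossing; AE_100 and t_100% from the endpoint."""
    values = {}
    for level in THRESHOLD_LEVELS:
        try:
            values[level] = crossing(vc.psi, vc.plc, level)
        except OutOfRangeError as exc:
            raise MissingThresholdError(level) from exc
    return ThresholdSet(
        ae12=values[12.0],
        ae50=values[50.0],
        ae88=values[88.0],
        ae100=float(vc.psi[-1]),
        t100=vc.endpoint_time / 3600.0,
    )


def average_curves(
    vcs: list[VulnerabilityCurve], grid_step: float = DEFAULT_PSI_GRID_STEP
) -> AveragedCurves:
    """Resample replicate curves to a common Ψ grid and summarize.

    Thresholds are computed per shoot and reported as mean ± SE (dispersion
    is only defined across shoots, not on the averaged curve).
    """
    if len(vcs) < 2:
        raise InvalidInputError("need at least 2 replicate curves to average")
    hi = min(float(vc.psi.max()) for vc in vcs)
    lo = max(float(vc.psi.min()) for vc in vcs)
    if hi - lo < grid_step:
        raise AlignmentError("replicate Ψ ranges have an empty intersection")
    grid = np.arange(hi, lo - 1e-12, -grid_step)
    stack = np.vstack(
        [np.interp(grid[::-1], vc.psi[::-1], vc.plc[::-1])[::-1] for vc in vcs]
    )
    plc_mean = stack.mean(axis=0)
    plc_se = stack.std(axis=0, ddof=1) / np.sqrt(len(vcs))
    per_shoot = [thresholds(vc) for vc in vcs]

    def _stat(fn):
        return {
            f: float(fn([getattr(t, f) for t in per_shoot]))
            for f in ("ae12", "ae50", "ae88", "ae100", "t100")
        }

    mean = _stat(np.mean)
    se = _stat(lambda v: np.std(v, ddof=1) / np.sqrt(len(v)))
    return AveragedCurves(
        psi_grid=grid,
        plc_mean=plc_mean,
        plc_se=plc_se,
        per_shoot=per_shoot,
        mean=ThresholdSet(**mean),
        se=se,
    )


def ae50_activity_regression(pairs) -> RegressionResult:
    """OLS of Ψ at maximum activity on AE_50 across cultivars, with R²."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidInputError("need >= 3 (ae50, psi_at_max_activity) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate design: all AE_50 values identical")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def compare_visual_counts(counts, cum: BinnedSeries, endpoint_s: float):
    """Deviation between normalized visual embolism counts and cumulative AE.

    Both series are expressed as % of their value at the endpoint; each count
    is compared with the AE percentage at the nearest grid time.  Returns
    ``(max_abs_deviation, mean_abs_deviation)`` in percentage points.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise InvalidInputError("counts must be (time, count) pairs")
    t = arr[:, 0]
    c = arr[:, 1]
    if np.any(np.diff(t) < 0):
        raise InvalidInputError("counts must be time-sorted")
    t_last = cum.t0 + (len(cum) - 1) * cum.dt
    if t.min() < cum.t0 or t.max() > t_last:
        raise OutOfRangeError("visual counts fall outside the recording span")
    in_window = t <= endpoint_s
    if not np.any(in_window) or c[in_window][-1] <= 0:
        raise InvalidInputError("final visual count before the endpoint must be > 0")
    c_end = c[in_window][-1]
    idx_end = int(round((endpoint_s - cum.t0) / cum.dt))
    idx_end = min(max(idx_end, 0), len(cum) - 1)
    ae_end = cum.values[idx_end]
    if ae_end <= 0:
        raise InvalidInputError("zero cumulative AE at the endpoint")
    idx = np.clip(np.round((t[in_window] - cum.t0) / cum.dt).astype(int), 0, len(cum) - 1)
    dev = np.abs(100.0 * c[in_window] / c_end - 100.0 * cum.values[idx] / ae_end)
    return float(dev.max()), float(dev.mean())
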