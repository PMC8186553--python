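"""Desorption curves and hydraulic capacitances from balance traces.

Mass loss of a dehydrating shoot is a surrogate for its change in water
content (ΔWC, g).  Plotted against the continuous Ψ_xylem axis it shows a
short pre-phase, an elastic phase I (water released from living tissue) and
an inelastic phase II (water released by embolizing xylem), separated by
two breakpoints of a two-breakpoint segmented regression.  The hydraulic
capacitance of each phase — C_el and C_inel, g MPa⁻¹ — is the magnitude of
the OLS slope of water loss against Ψ within that phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .exceptions import (
    AlignmentError,
    DegeneratePhaseError,
    InsufficientPhaseDataError,
    InvalidInputError,
)
from .psi_axis import PsiAxis
from .segfit import fit_segmented

__all__ = [
    "MassTrace",
    "DesorptionCurve",
    "build_dc",
    "dc_breakpoints",
    "capacitances",
]

MIN_PHASE_POINTS = 3


@dataclass
class MassTrace:
    """Sample mass (g) vs time (s since excision) from a weighing balance."""

    times: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.times.shape != self.mass.shape or self.times.ndim != 1:
            raise InvalidInputError("times and mass must match in length")
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing (>= 2 samples)")
        if np.any(self.mass <= 0):
            raise InvalidInputError("mass must stay positive")


@dataclass
class DesorptionCurve:
    """Cumulative water loss (g) vs Ψ (MPa) with phase breakpoints and capacitances."""

    psi: np.ndarray
    water_loss: np.ndarray
    bp1: float
    bp2: float
    c_el: float
    c_inel: float

    def __post_init__(self):
        if self.bp1 <= self.bp2:
            raise InvalidInputError("bp1 must be less negative than bp2")
        if self.c_el < 0 or self.c_inel < 0:
            raise InvalidInputError("capacitances are reported as positive magnitudes")


def build_dc(mass: MassTrace, axis: PsiAxis):
    """Resample ΔWC = mass(0) − mass(t) onto the Ψ-axis grid.

    Balance jitter can make the loss locally non-monotone; an isotonic
    projection restores the physical non-decrease along drying.  Returns
    ``(psi, water_loss)`` arrays restricted to the temporal overlap.
    """
    t_axis = axis.times
    if mass.times[0] > t_axis[-1] or mass.times[-1] < t_axis[0]:
        raise AlignmentError("mass trace and Ψ axis do not overlap in time")
    in_span = (t_axis >= mass.times[0] - axis.dt / 2) & (
        t_axis <= mass.times[-1] + axis.dt / 2
    )
    t_grid = t_axis[in_span]
    if t_grid.size < 2:
        raise AlignmentError("fewer than 2 grid points overlap the mass trace")
    mass0 = float(np.interp(t_axis[0], mass.times, mass.mass))
    loss = mass0 - np.interp(t_grid, mass.times, mass.mass)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    loss = iso.fit_transform(np.arange(loss.size, dtype=float), loss)
    return axis.psi[in_span], loss


def dc_breakpoints(psi, water_loss, psi_floor: float | None = None):
    """Locate the two phase breakpoints of a desorption curve.

    Fits a continuous two-breakpoint segmented regression of water loss on
    Ψ; returns ``(bp1, bp2)`` with bp1 the less negative (start of phase I).
    ``psi_floor`` (typically the cultivar AE_100) truncates the curve on the
    dry end: the phase structure is defined only down to full embolism, and
    including the tail beyond it lets Ψ-axis distortion there consume a
    breakpoint.  A desorption curve with no phase structure (a single
    straight line) raises :class:`DegeneratePhaseError`.
    """
    psi = np.asarray(psi, dtype=float)
    loss = np.asarray(water_loss, dtype=float)
    if psi_floor is not None:
        keep = psi >= psi_floor
        psi, loss = psi[keep], loss[keep]
    try:
        ols = fit_segmented(psi, loss, 0)
        y_scale = max(float(np.var(loss)) * loss.size, 1e-30)
        if ols.sse <= 1e-12 * y_scale:
            raise DegeneratePhaseError(
                "desorption curve is a single straight line; no phase breakpoints"
            )
        fit = fit_segmented(psi, loss, 2)
    except InvalidInputError as exc:
        raise DegeneratePhaseError(
            f"two-breakpoint fit unidentifiable on this curve: {exc}"
        ) from exc
    slopes = np.asarray(fit.slopes)
    if np.ptp(slopes) <= 1e-6 * max(float(np.max(np.abs(slopes))), 1e-30):
        raise DegeneratePhaseError("segment slopes indistinguishable; no phases")
    bp_lo, bp_hi = sorted(fit.breakpoints)
    return float(bp_hi), float(bp_lo)


def _phase_slope(psi, loss, lo, hi, label):
    mask = (psi >= lo) & (psi <= hi)
    if np.count_nonzero(mask) < MIN_PHASE_POINTS:
        raise InsufficientPhaseDataError(
            f"fewer than {MIN_PHASE_POINTS} points in the {label} window "
            f"[{lo:.3f}, {hi:.3f}] MPa"
        )
    if np.ptp(psi[mask]) == 0:
        raise InsufficientPhaseDataError(f"no Ψ spread inside the {label} window")
    return float(stats.linregress(psi[mask], loss[mask]).slope)


def capacitances(psi, water_loss, bp1: float, bp2: float, ae100: float):
    """Elastic and inelastic hydraulic capacitances (g MPa⁻¹, positive).

    C_el is the |slope| of water loss vs Ψ over phase I (bp2 ≤ Ψ ≤ bp1);
    C_inel over phase II, which runs from the second breakpoint down to
    AE_100 (ae100 ≤ Ψ ≤ bp2).
    """
    if not (bp1 > bp2 >= ae100):
        raise InvalidInputError(
            f"phase windows require bp1 > bp2 >= ae100, got {bp1}, {bp2}, {ae100}"
        )
    psi = np.asarray(psi, dtype=float)
    loss = np.asarray(water_loss, dtype=float)
    c_el = abs(_phase_slope(psi, loss, bp2, bp1, "elastic phase I"))
    c_inel = abs(_phase_slope(psi, loss, ae100, bp2, "inelastic phase II"))
    return c_el, c_inel
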