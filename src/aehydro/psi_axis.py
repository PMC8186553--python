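"""Continuous xylem water potential axis from dendrometer shrinkage.

The dendrometer gives a continuous radial-displacement trace; the pressure
chamber gives sparse Ψ_xylem point readings.  A one-breakpoint segmented
regression of Ψ on relative radial shrinkage (the stress–strain relation,
which shows an elastic and an inelastic phase) turns the continuous trace
into a continuous Ψ(t) axis on the 5-min acoustic grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .exceptions import InvalidInputError
from .segfit import BinnedSeries, SegmentedFit, fit_segmented

__all__ = [
    "DendroTrace",
    "PsiObservation",
    "PsiAxis",
    "relative_shrinkage",
    "fit_stress_strain",
    "psi_timeline",
]

DEFAULT_BIN_S = 300.0


@dataclass
class DendroTrace:
    """Radial displacement (μm) vs time (s) plus the reference diameter d_i (mm)."""

    times: np.ndarray
    displacement_um: np.ndarray
    reference_diameter_mm: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        if self.times.shape != self.displacement_um.shape or self.times.ndim != 1:
            raise InvalidInputError("times and displacement must match in length")
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing (>= 2 samples)")
        if self.reference_diameter_mm <= 0:
            raise InvalidInputError("reference diameter d_i must be positive")


@dataclass(frozen=True)
class PsiObservation:
    """A single pressure-chamber reading: Ψ_xylem (MPa, <= 0) at time (s)."""

    time: float
    psi: float

    def __post_init__(self):
        if self.psi > 0:
            raise InvalidInputError(
                f"Ψ_xylem must be <= 0 MPa (tension), got {self.psi}"
            )


@dataclass
class PsiAxis:
    """Ψ_xylem (MPa) on the acoustic bin grid, non-increasing in time."""

    t0: float
    dt: float
    psi: np.ndarray
    source_fit: SegmentedFit | None = None

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        if np.any(np.diff(self.psi) > 1e-9):
            raise InvalidInputError("Ψ axis must be non-increasing in time")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.psi.size)

    def psi_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.psi)

    def __len__(self):
        return self.psi.size


def _as_observations(obs) -> list[PsiObservation]:
    if isinstance(obs, pd.DataFrame):
        return [
            PsiObservation(float(t), float(p))
            for t, p in zip(obs["time_s"], obs["psi_mpa"])
        ]
    return [o if isinstance(o, PsiObservation) else PsiObservation(*o) for o in obs]


def relative_shrinkage(dendro: DendroTrace, bin_s: float = DEFAULT_BIN_S) -> BinnedSeries:
    """Relative radial shrinkage Δd/d_i (μm mm⁻¹) resampled to the AE bin grid.

    Δd(t) = displacement(0) − displacement(t), so shrinkage grows positive as
    the stem contracts; the value at t = 0 is exactly 0.
    """
    if bin_s <= 0:
        raise InvalidInputError("bin width must be positive")
    t_end = dendro.times[-1]
    n_bins = int(np.floor(t_end / bin_s))
    if n_bins < 1:
        raise InvalidInputError("dendrometer trace shorter than one bin")
    grid = bin_s * np.arange(n_bins + 1)
    disp = np.interp(grid, dendro.times, dendro.displacement_um)
    disp0 = np.interp(0.0, dendro.times, dendro.displacement_um)
    shrink = (disp0 - disp) / dendro.reference_diameter_mm
    shrink[0] = 0.0
    return BinnedSeries(0.0, bin_s, shrink)


def fit_stress_strain(shrinkage: BinnedSeries, obs, n_breakpoints: int = 1) -> SegmentedFit:
    """Segmented-linear stress–strain fit: Ψ as a function of shrinkage.

    Each Ψ reading is matched to the shrinkage value at the nearest grid time
    (≤ half a bin offset; readings outside the trace span are dropped).  When
    the segmented fit is unidentifiable — too few observations on one side of
    every candidate breakpoint, or the relation is effectively a single line —
    the fit falls back to ordinary least squares with ``fallback=True`` and a
    warning.
    """
    observations = _as_observations(obs)
    if len(observations) < 6:
        raise InvalidInputError(
            f"need >= 6 Ψ observations spanning both phases, got {len(observations)}"
        )
    times = shrinkage.times
    x, y = [], []
    for o in observations:
        idx = int(round((o.time - shrinkage.t0) / shrinkage.dt))
        if idx < 0 or idx >= len(times):
            continue  # reading outside the dendrometer span
        x.append(shrinkage.values[idx])
        y.append(o.psi)
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size < 6:
        raise InvalidInputError("fewer than 6 Ψ observations overlap the trace")

    ols = fit_segmented(x, y, 0)
    if n_breakpoints == 0:
        return ols
    y_scale = max(float(np.var(y)) * y.size, 1e-30)
    if ols.sse <= 1e-12 * y_scale:
        warnings.warn(
            "stress–strain relation is effectively linear; "
            "falling back to an unsegmented fit",
            stacklevel=2,
        )
        return replace(ols, fallback=True)
    try:
        seg = fit_segmented(x, y, n_breakpoints)
    except InvalidInputError:
        warnings.warn(
            "segmented stress–strain fit unidentifiable; falling back to OLS",
            stacklevel=2,
        )
        return replace(ols, fallback=True)
    slopes = np.asarray(seg.slopes)
    spread = np.ptp(slopes)
    if spread <= 1e-6 * max(np.max(np.abs(slopes)), 1e-30):
        warnings.warn(
            "segmented fit slopes indistinguishable; falling back to OLS",
            stacklevel=2,
        )
        return replace(ols, fallback=True)
    return seg


def psi_timeline(fit: SegmentedFit, shrinkage: BinnedSeries) -> PsiAxis:
    """Map shrinkage through the stress–strain fit and enforce physics.

    Ψ cannot increase during bench dehydration, so noise-induced inversions
    are removed by an L2 isotonic (pool-adjacent-violators) projection onto
    non-increasing sequences.
    """
    raw = np.asarray(fit.predict(shrinkage.values), dtype=float)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    mono = iso.fit_transform(np.arange(raw.size, dtype=float), raw)
    return PsiAxis(shrinkage.t0, shrinkage.dt, mono, source_fit=fit)
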