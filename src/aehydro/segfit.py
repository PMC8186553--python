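"""Shared numerics: segmented least squares, finite differences, level crossings.

Everything downstream leans on three primitives:

* :func:`fit_segmented` — continuous piecewise-linear least squares with a
  grid-search initialisation over candidate breakpoints (midpoints of
  consecutive distinct predictor values) followed by Nelder–Mead refinement
  of the breakpoint positions.  This powers both the stress–strain
  (shrinkage vs Ψ) regression and the two-breakpoint desorption-curve fit.
* :func:`finite_derivative` — iterated central differences of a fixed time
  span on evenly binned series (one-sided stencils at the edges), used for
  the acoustic activity curve (order 1) and the endpoint detector (order 3).
* :func:`crossing` — first monotone level crossing by linear interpolation,
  used to read AE_12/AE_50/AE_88 off a vulnerability curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .exceptions import InvalidInputError, InvalidWindowError, OutOfRangeError

__all__ = [
    "SegmentedFit",
    "BinnedSeries",
    "fit_segmented",
    "finite_derivative",
    "crossing",
]

#: minimum number of data points each segment must contain for its slope to
#: be identifiable
MIN_SEGMENT_POINTS = 3


@dataclass(frozen=True)
class SegmentedFit:
    """A continuous piecewise-linear model ``y = f(x)``.

    ``breakpoints`` are strictly increasing x-values strictly inside the data
    range; there is one slope per segment (``len(slopes) ==
    len(breakpoints) + 1``) and the function is continuous at every
    breakpoint by construction.
    """

    breakpoints: tuple[float, ...]
    intercept: float
    slopes: tuple[float, ...]
    sse: float
    n_points: int
    fallback: bool = False  # set when a segmented fit degraded to plain OLS

    def __post_init__(self):
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise InvalidInputError(
                "need exactly one slope per segment "
                f"({len(self.breakpoints)} breakpoints, {len(self.slopes)} slopes)"
            )
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size and np.any(np.diff(bp) <= 0):
            raise InvalidInputError("breakpoints must be strictly increasing")
        if self.sse < -1e-9:
            raise InvalidInputError("sse must be non-negative")

    def predict(self, x):
        """Evaluate the fitted function at ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slopes[0] * x
        for bp, s_prev, s_next in zip(
            self.breakpoints, self.slopes[:-1], self.slopes[1:]
        ):
            out = out + (s_next - s_prev) * np.clip(x - bp, 0.0, None)
        return out if out.ndim else float(out)

    def __call__(self, x):
        return self.predict(x)


@dataclass
class BinnedSeries:
    """Evenly sampled series: value ``values[i]`` at time ``t0 + i*dt`` (s)."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise InvalidInputError("bin width dt must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InvalidInputError("a binned series needs at least 2 values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def __len__(self):
        return self.values.size

    def value_at(self, t: float) -> float:
        """Linear interpolation at time ``t`` (clamped to the series span)."""
        return float(np.interp(t, self.times, self.values))


# ---------------------------------------------------------------------------
# segmented least squares
# ---------------------------------------------------------------------------


def _design(x: np.ndarray, breakpoints) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in breakpoints:
        cols.append(np.clip(x - b, 0.0, None))
    return np.column_stack(cols)


def _sse_at(x, y, breakpoints) -> float:
    X = _design(x, breakpoints)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _segment_counts_ok(xs: np.ndarray, breakpoints, min_pts: int) -> bool:
    """True when every segment delimited by ``breakpoints`` holds >= min_pts points."""
    edges = [-np.inf, *breakpoints, np.inf]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.count_nonzero((xs > lo) & (xs <= hi)) < min_pts:
            return False
    return True


def _candidate_breakpoints(xs: np.ndarray, min_pts: int) -> np.ndarray:
    """Midpoints of consecutive distinct sorted x that leave >= min_pts on each side."""
    distinct = np.unique(xs)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    keep = [
        m
        for m in mids
        if np.count_nonzero(xs <= m) >= min_pts
        and np.count_nonzero(xs > m) >= min_pts
    ]
    return np.asarray(keep, dtype=float)


def _grid_search(xs, ys, n_breakpoints, min_pts):
    """Exhaustive search over combinations of candidate midpoints.

    Normal equations are assembled from precomputed cross-sums so the pair
    grid stays cheap (O(C^2) small solves instead of O(C^2) full lstsq).
    Ties are broken toward the lexicographically smallest breakpoint tuple
    by iterating combinations in sorted order with a strict improvement test.
    """
    cand = _candidate_breakpoints(xs, min_pts)
    if cand.size < n_breakpoints:
        raise InvalidInputError(
            f"only {cand.size} admissible breakpoint candidates for "
            f"{n_breakpoints} requested breakpoints"
        )
    n = xs.size
    # hinge basis per candidate: R[c, i] = max(xs[i] - cand[c], 0)
    R = np.clip(xs[None, :] - cand[:, None], 0.0, None)
    S = {
        "1": float(n),
        "x": float(xs.sum()),
        "xx": float(xs @ xs),
        "y": float(ys.sum()),
        "xy": float(xs @ ys),
        "yy": float(ys @ ys),
    }
    A1 = R.sum(axis=1)
    Ax = R @ xs
    Ay = R @ ys
    cross = R @ R.T  # cross[i, j] = sum_k R_i R_j (diagonal: sum R^2)

    best_sse = np.inf
    best_combo = None
    # xs is sorted: points at or below cand[c] = pos[c], so per-segment counts
    # are differences of these positions
    pos = np.searchsorted(xs, cand, side="right")
    for combo in itertools.combinations(range(cand.size), n_breakpoints):
        bounds = (0, *(pos[c] for c in combo), n)
        if any(b - a < min_pts for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        bps = cand[list(combo)]
        p = 2 + n_breakpoints
        G = np.empty((p, p))
        v = np.empty(p)
        G[0, 0] = S["1"]
        G[0, 1] = G[1, 0] = S["x"]
        G[1, 1] = S["xx"]
        v[0] = S["y"]
        v[1] = S["xy"]
        for a, ci in enumerate(combo):
            G[0, 2 + a] = G[2 + a, 0] = A1[ci]
            G[1, 2 + a] = G[2 + a, 1] = Ax[ci]
            v[2 + a] = Ay[ci]
            for b_, cj in enumerate(combo):
                G[2 + a, 2 + b_] = cross[ci, cj]
        try:
            beta = np.linalg.solve(G, v)
        except np.linalg.LinAlgError:
            continue
        sse = S["yy"] - beta @ v
        if not np.isfinite(sse):
            continue
        if best_combo is None or sse < best_sse - 1e-15 * max(1.0, abs(best_sse)):
            best_sse = sse
            best_combo = bps
    if best_combo is None:
        raise InvalidInputError("no admissible breakpoint combination found")
    return np.asarray(best_combo, dtype=float), max(float(best_sse), 0.0)


def _refine(xs, ys, bps0, sse0, min_pts):
    """Nelder–Mead polish of breakpoint positions; never worse than the grid."""
    span = xs[-1] - xs[0]
    penalty = sse0 * 10 + float(ys @ ys) + 1.0

    def objective(b):
        b = np.sort(b)
        if np.any(np.diff(b) <= 1e-12 * span) if b.size > 1 else False:
            return penalty
        if b[0] <= xs[0] or b[-1] >= xs[-1]:
            return penalty
        if not _segment_counts_ok(xs, b, min_pts):
            return penalty
        return _sse_at(xs, ys, b)

    res = minimize(
        objective,
        bps0,
        method="Nelder-Mead",
        options={"xatol": 1e-10 * max(span, 1.0), "fatol": 1e-12 * (sse0 + 1.0),
                 "maxiter": 2000},
    )
    b = np.sort(res.x)
    if objective(res.x) < sse0 and b[0] > xs[0] and b[-1] < xs[-1]:
        return b, _sse_at(xs, ys, b)
    return bps0, sse0


def fit_segmented(x, y, n_breakpoints: int, *,
                  min_segment_points: int = MIN_SEGMENT_POINTS) -> SegmentedFit:
    """Continuous piecewise-linear least-squares fit with ``n_breakpoints`` knots.

    With ``n_breakpoints == 0`` this reduces exactly to ordinary least
    squares.  Breakpoints are constrained to leave at least
    ``min_segment_points`` data points in every segment so all slopes are
    identifiable.

    Raises
    ------
    InvalidInputError
        on mismatched lengths, too few (or too few distinct) x values, or
        all-equal x.
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise InvalidInputError("x and y must be finite")
    if int(n_breakpoints) != n_breakpoints or n_breakpoints < 0:
        raise InvalidInputError("n_breakpoints must be a non-negative integer")
    n_breakpoints = int(n_breakpoints)
    if xs.size < 2 * (n_breakpoints + 2):
        raise InvalidInputError(
            f"need at least {2 * (n_breakpoints + 2)} points for "
            f"{n_breakpoints} breakpoints, got {xs.size}"
        )
    if np.unique(xs).size < n_breakpoints + 2:
        raise InvalidInputError(
            "not enough distinct x values (all-equal x is degenerate)"
        )

    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]

    if n_breakpoints == 0:
        X = _design(xs, ())
        beta, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
        r = ys - X @ beta
        return SegmentedFit((), float(beta[0]), (float(beta[1]),),
                            float(r @ r), xs.size)

    bps, sse = _grid_search(xs, ys, n_breakpoints, min_segment_points)
    bps, sse = _refine(xs, ys, bps, sse, min_segment_points)

    X = _design(xs, bps)
    beta, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
    r = ys - X @ beta
    slopes = tuple(np.cumsum(np.concatenate(([beta[1]], beta[2:]))).tolist())
    return SegmentedFit(tuple(bps.tolist()), float(beta[0]), slopes,
                        float(r @ r), xs.size)


# ---------------------------------------------------------------------------
# finite differences
# ---------------------------------------------------------------------------


def finite_derivative(series: BinnedSeries, window: float, order: int) -> BinnedSeries:
    """Iterated finite-difference derivative of span ``window`` seconds.

    Each pass applies a central difference spanning ``window`` (value at
    ``t + w/2`` minus value at ``t - w/2``, divided by the actual span);
    near the edges the stencil degrades gracefully to a one-sided
    difference over whatever span is available.  ``order`` passes give the
    order-th derivative estimate on the same bin grid; a linear input
    yields an exactly constant first derivative and zero higher orders.
    """
    if order not in (1, 2, 3):
        raise InvalidInputError(f"order must be 1, 2 or 3, got {order}")
    dt = series.dt
    if window < 2 * dt:
        raise InvalidWindowError(
            f"window {window} s shorter than two bins ({2 * dt} s)"
        )
    h = max(1, int(round(window / (2 * dt))))
    n = series.values.size
    if n < h + 2:
        raise InvalidInputError(
            f"series of {n} bins too short for half-window of {h} bins"
        )
    v = series.values
    idx = np.arange(n)
    hi = np.minimum(idx + h, n - 1)
    lo = np.maximum(idx - h, 0)
    for _ in range(order):
        v = (v[hi] - v[lo]) / ((hi - lo) * dt)
    return BinnedSeries(series.t0, dt, v)


# ---------------------------------------------------------------------------
# monotone level crossing
# ---------------------------------------------------------------------------


def crossing(x, y, level: float) -> float:
    """x-value of the first crossing of ``level`` along a monotone polyline.

    ``y`` is forced non-decreasing (running maximum) before interpolation;
    when ``level`` coincides with a node value the node's x is returned
    exactly.  ``x`` may run in either direction (e.g. Ψ decreasing while
    PLC increases).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    ya = np.maximum.accumulate(ya)
    if level < ya[0] or level > ya[-1]:
        raise OutOfRangeError(
            f"level {level} outside series range [{ya[0]}, {ya[-1]}]"
        )
    i = int(np.searchsorted(ya, level, side="left"))
    if ya[i] == level:
        return float(xa[i])
    frac = (level - ya[i - 1]) / (ya[i] - ya[i - 1])
    return float(xa[i - 1] + frac * (xa[i] - xa[i - 1]))
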