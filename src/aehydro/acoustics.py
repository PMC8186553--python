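"""Acoustic-emission event processing.

Ultrasonic acoustic emissions accompany embolism formation in dehydrating
xylem.  The processing chain mirrors standard acoustic vulnerability
analysis: filter events to the 20–1000 kHz band above the 28 dB_AE noise
floor, cumulate counts in 5-min bins, differentiate over 15 min to get an
activity curve, detect the endpoint of embolism formation as the first
post-peak local maximum of the third derivative (where activity decreases
most strongly), and rescale cumulative AE between zero and the endpoint to
percent loss of conductivity (PLC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, NoEndpointError, OutOfRangeError
from .segfit import BinnedSeries, finite_derivative

__all__ = [
    "AEEvent",
    "EVENT_COLUMNS",
    "events_frame",
    "filter_events",
    "cumulate",
    "ae_activity",
    "detect_endpoint",
    "to_plc",
]

EVENT_COLUMNS = ("time_s", "amplitude_dbae", "peak_freq_khz")

DEFAULT_BIN_S = 300.0
DEFAULT_ACTIVITY_WINDOW_S = 900.0
DEFAULT_D3_WINDOW_S = 9000.0  # 2.5 h, configurable 2–3 h
DEFAULT_MIN_AMPLITUDE_DBAE = 28.0
DEFAULT_BAND_KHZ = (20.0, 1000.0)


@dataclass(frozen=True)
class AEEvent:
    """One acoustic hit: time since excision (s), amplitude (dB_AE), peak frequency (kHz)."""

    time: float
    amplitude: float
    peak_frequency: float

    def __post_init__(self):
        if self.time < 0 or self.amplitude <= 0 or self.peak_frequency <= 0:
            raise InvalidInputError(
                "AE event needs time >= 0 and positive amplitude/frequency"
            )


def events_frame(events) -> pd.DataFrame:
    """Coerce an event collection into the canonical event table."""
    if isinstance(events, pd.DataFrame):
        missing = set(EVENT_COLUMNS) - set(events.columns)
        if missing:
            raise InvalidInputError(f"event table missing columns {sorted(missing)}")
        df = events.loc[:, list(EVENT_COLUMNS)].copy()
    else:
        rows = [
            (e.time, e.amplitude, e.peak_frequency) if isinstance(e, AEEvent) else tuple(e)
            for e in events
        ]
        df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    df = df.astype(float)
    if len(df):
        if (df["time_s"] < 0).any():
            raise InvalidInputError("event times must be >= 0 (seconds since excision)")
        if (df["amplitude_dbae"] <= 0).any() or (df["peak_freq_khz"] <= 0).any():
            raise InvalidInputError("amplitudes and frequencies must be positive")
    return df


def filter_events(
    events,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE_DBAE,
    band: tuple[float, float] = DEFAULT_BAND_KHZ,
) -> pd.DataFrame:
    """Retain events with amplitude >= ``min_amplitude`` inside the inclusive band.

    Stands in for the acquisition hardware's band-pass filter and noise
    threshold; events are returned time-sorted (stable for ties).
    """
    df = events_frame(events)
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    keep = (
        (df["amplitude_dbae"] >= min_amplitude)
        & (df["peak_freq_khz"] >= band[0])
        & (df["peak_freq_khz"] <= band[1])
    )
    return df.loc[keep].reset_index(drop=True)


def cumulate(
    events, bin_s: float = DEFAULT_BIN_S, span_s: float | None = None
) -> BinnedSeries:
    """Cumulative retained-event count on bin edges 0, bin, 2·bin, …

    The first value is anchored at 0 (counts strictly after t = 0 fall in the
    first bin) and the last equals the total retained count.  ``span_s``
    extends the grid beyond the last event (e.g. to the full recording span);
    it is required to give an empty stream a meaningful extent.
    """
    df = events_frame(events)
    if bin_s <= 0:
        raise InvalidInputError("bin width must be positive")
    t_max = float(df["time_s"].max()) if len(df) else 0.0
    if span_s is not None:
        t_max = max(t_max, float(span_s))
    n_bins = max(int(np.ceil(t_max / bin_s)), 1)
    edges = bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(df["time_s"].to_numpy(), bins=edges)
    values = np.concatenate(([0.0], np.cumsum(counts, dtype=float)))
    return BinnedSeries(0.0, bin_s, values)


def ae_activity(
    cum: BinnedSeries, window_s: float = DEFAULT_ACTIVITY_WINDOW_S
) -> BinnedSeries:
    """AE activity (hits h⁻¹): 15-min first derivative of cumulative AE."""
    if len(cum) < window_s / cum.dt + 1:
        raise InvalidInputError(
            f"cumulative series of {len(cum)} bins too short for a "
            f"{window_s:.0f}-s activity window"
        )
    d1 = finite_derivative(cum, window_s, order=1)
    return BinnedSeries(d1.t0, d1.dt, d1.values * 3600.0)


def detect_endpoint(
    cum: BinnedSeries,
    d3_window_s: float = DEFAULT_D3_WINDOW_S,
    activity_window_s: float = DEFAULT_ACTIVITY_WINDOW_S,
    prominence: float = 0.5,
) -> float:
    """Endpoint of embolism formation (s): the AE_100 time.

    After the activity peak, embolism formation tails off; the time where
    activity decreases most strongly is the local maximum of the third
    derivative of cumulative AE (computed over a 2–3 h interval, default
    2.5 h).  Among post-peak local maxima the first one reaching at least
    ``prominence`` of the strongest is taken, so a marginal early wiggle
    cannot pre-empt the true shoulder; ties resolve to the earliest bin.
    """
    activity = ae_activity(cum, activity_window_s)
    vals = activity.values
    if np.ptp(vals) <= 1e-12 * max(1.0, float(np.max(np.abs(vals)))):
        raise NoEndpointError("activity curve has no peak structure")
    peak_idx = int(np.argmax(vals))
    if peak_idx >= len(vals) - 1:
        raise NoEndpointError("activity peak at the end of the recording")

    d3 = finite_derivative(cum, d3_window_s, order=3).values
    interior = np.arange(1, d3.size - 1)
    is_local_max = (d3[interior] > d3[interior - 1]) & (d3[interior] >= d3[interior + 1])
    candidates = interior[is_local_max & (interior > peak_idx)]
    if candidates.size == 0:
        raise NoEndpointError(
            "no local maximum of the third derivative after the activity peak; "
            "the recording may end too early"
        )
    post_max = float(np.max(d3[candidates]))
    if post_max > 0:
        chosen = candidates[d3[candidates] >= prominence * post_max][0]
    else:
        chosen = candidates[int(np.argmax(d3[candidates]))]
    return float(cum.t0 + chosen * cum.dt)


def to_plc(cum: BinnedSeries, endpoint_s: float) -> BinnedSeries:
    """Rescale cumulative AE to PLC (%): 0 at start, 100 at the endpoint.

    The series is truncated at the endpoint bin; PLC(endpoint) = 100.
    """
    idx = int(round((endpoint_s - cum.t0) / cum.dt))
    if idx < 1 or idx >= len(cum):
        raise OutOfRangeError(f"endpoint {endpoint_s} s outside the series")
    total = cum.values[idx]
    if total <= 0:
        raise InvalidInputError("zero cumulative AE at the endpoint")
    return BinnedSeries(cum.t0, cum.dt, 100.0 * cum.values[: idx + 1] / total)
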