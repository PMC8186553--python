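"""Xylem anatomical traits from per-vessel measurement tables.

Traits summarize the safety–efficiency trade-off of the xylem: wide vessels
(high hydraulically weighted diameter d_h) conduct efficiently but embolize
readily; thick walls relative to their span (high conduit wall
reinforcement, CWR) resist implosion; highly grouped vessels (vessel
grouping index V_g) exchange water with neighbours.  Tables come from image
analysis of stained cross-sections; both protoxylem and metaxylem records
are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    EmptySelectionError,
    InvalidInputError,
    MissingMeasurementError,
)

__all__ = [
    "VESSEL_COLUMNS",
    "SectionGeometry",
    "AnatomySummary",
    "diameter_from_area",
    "hydraulic_diameter",
    "conduit_wall_reinforcement",
    "grouping_index",
    "summarize_section",
]

VESSEL_COLUMNS = ("vessel_id", "organ", "area_um2", "t_um", "b_um", "group_id")

DEFAULT_CWR_WINDOW = 0.10


@dataclass(frozen=True)
class SectionGeometry:
    """Stem cross-section areas (mm²) for parenchyma-fraction computation."""

    stem_area_mm2: float
    parenchyma_area_mm2: float

    def __post_init__(self):
        if not (0 <= self.parenchyma_area_mm2 <= self.stem_area_mm2):
            raise InvalidInputError(
                "need 0 <= parenchyma area <= stem area (both mm²)"
            )


@dataclass(frozen=True)
class AnatomySummary:
    a_ind_mean_um2: float
    a_total_mm2: float
    a_stem_mm2: float
    pct_parenchyma: float
    d_h_um: float
    n_vessel: int
    v_g: float
    cwr: float | None  # None when no vessel carries wall measurements


def diameter_from_area(area):
    """Equivalent circular diameter d = 2·√(A/π), μm from μm²."""
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise InvalidInputError("vessel areas must be positive")
    d = 2.0 * np.sqrt(a / np.pi)
    return d if d.ndim else float(d)


def hydraulic_diameter(diameters) -> float:
    """Hydraulically weighted diameter: fourth root of the mean fourth power.

    Weights wide vessels, which dominate conductance (∝ d⁴ by Hagen–
    Poiseuille); always ≥ the arithmetic mean diameter.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise InvalidInputError("need at least one diameter")
    if np.any(d <= 0):
        raise InvalidInputError("diameters must be positive")
    return float(np.mean(d**4) ** 0.25)


def conduit_wall_reinforcement(
    records: pd.DataFrame,
    d_h: float | None = None,
    window: float = DEFAULT_CWR_WINDOW,
) -> float:
    """CWR = (t/b)² averaged over vessels with diameter near d_h.

    ``t`` is the double wall thickness and ``b`` the conduit wall span of a
    vessel pair; the ratio is evaluated for vessels whose diameter lies
    within ±``window`` (fractional) of the hydraulically weighted diameter,
    falling back to the single nearest measured vessel when none does.  The
    ratio is averaged first, then squared.
    """
    has_walls = records.dropna(subset=["t_um", "b_um"])
    if has_walls.empty:
        raise MissingMeasurementError(
            "no vessel record carries both wall thickness (t) and wall span (b)"
        )
    if d_h is None:
        d_h = hydraulic_diameter(diameter_from_area(records["area_um2"].to_numpy()))
    d = diameter_from_area(has_walls["area_um2"].to_numpy())
    near = np.abs(d - d_h) <= window * d_h
    if not np.any(near):
        near = np.zeros(d.size, dtype=bool)
        near[int(np.argmin(np.abs(d - d_h)))] = True
    ratio = has_walls["t_um"].to_numpy()[near] / has_walls["b_um"].to_numpy()[near]
    return float(np.mean(ratio) ** 2)


def grouping_index(records: pd.DataFrame) -> float:
    """V_g: total vessels divided by distinct vessel groupings (≥ 1)."""
    if records.empty:
        raise InvalidInputError("need at least one vessel record")
    return float(len(records) / records["group_id"].nunique())


def summarize_section(
    records: pd.DataFrame,
    geometry: SectionGeometry,
    organ: str | None = None,
    cwr_window: float = DEFAULT_CWR_WINDOW,
) -> AnatomySummary:
    """All anatomical traits for one organ (``stem`` / ``leaf_sheath``) or combined."""
    df = records if organ is None else records[records["organ"] == organ]
    if df.empty:
        raise EmptySelectionError(f"no vessel records for organ filter {organ!r}")
    areas = df["area_um2"].to_numpy(dtype=float)
    diameters = diameter_from_area(areas)
    d_h = hydraulic_diameter(diameters)
    try:
        cwr = conduit_wall_reinforcement(df, d_h=d_h, window=cwr_window)
    except MissingMeasurementError:
        cwr = None
    return AnatomySummary(
        a_ind_mean_um2=float(areas.mean()),
        a_total_mm2=float(areas.sum() / 1e6),
        a_stem_mm2=geometry.stem_area_mm2,
        pct_parenchyma=100.0 * geometry.parenchyma_area_mm2 / geometry.stem_area_mm2,
        d_h_um=d_h,
        n_vessel=int(len(df)),
        v_g=grouping_index(df),
        cwr=cwr,
    )
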