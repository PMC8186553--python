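"""CSV readers/writers and the experiment configuration surface.

All on-disk formats are plain comma-separated UTF-8 with a header row and
"." decimals; times are seconds since excision, Ψ is negative MPa (a
positive Ψ in an input file is rejected, never silently sign-flipped).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acoustics import EVENT_COLUMNS, events_frame
from .anatomy import VESSEL_COLUMNS, SectionGeometry
from .desorption import MassTrace
from .exceptions import InvalidInputError
from .psi_axis import DendroTrace, PsiAxis

__all__ = [
    "ExperimentConfig",
    "read_ae_events", "write_ae_events",
    "read_dendro", "write_dendro",
    "read_mass", "write_mass",
    "read_psi_obs", "write_psi_obs",
    "read_psi_axis", "write_psi_axis",
    "read_vessels", "write_vessels",
    "read_geometry", "write_geometry",
]

_FLOAT_FMT = "%.6g"


def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path} missing columns {sorted(missing)}")
    return df


def read_ae_events(path) -> pd.DataFrame:
    """AE event table: ``time_s, amplitude_dbae, peak_freq_khz``."""
    return events_frame(_read_csv(path, EVENT_COLUMNS))


def write_ae_events(events: pd.DataFrame, path) -> None:
    events_frame(events).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dendro(path, reference_diameter_mm: float) -> DendroTrace:
    """Dendrometer trace: ``time_s, displacement_um`` (d_i comes from config)."""
    df = _read_csv(path, ("time_s", "displacement_um"))
    return DendroTrace(
        df["time_s"].to_numpy(float),
        df["displacement_um"].to_numpy(float),
        reference_diameter_mm,
    )


def write_dendro(trace: DendroTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "displacement_um": trace.displacement_um}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_mass(path) -> MassTrace:
    """Balance trace: ``time_s, mass_g``."""
    df = _read_csv(path, ("time_s", "mass_g"))
    return MassTrace(df["time_s"].to_numpy(float), df["mass_g"].to_numpy(float))


def write_mass(trace: MassTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "mass_g": trace.mass}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_psi_obs(path) -> pd.DataFrame:
    """Pressure-chamber readings: ``time_s, psi_mpa`` with Ψ <= 0."""
    df = _read_csv(path, ("time_s", "psi_mpa"))
    if (df["psi_mpa"] > 0).any():
        raise InvalidInputError(
            f"{path}: positive Ψ found — Ψ_xylem must be negative MPa "
            "(sign conventions are not auto-corrected)"
        )
    return df.astype(float)


def write_psi_obs(obs: pd.DataFrame, path) -> None:
    obs.loc[:, ["time_s", "psi_mpa"]].to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_psi_axis(path) -> PsiAxis:
    """Continuous Ψ axis on an even grid: ``time_s, psi_mpa``."""
    df = _read_csv(path, ("time_s", "psi_mpa"))
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise InvalidInputError(f"{path}: Ψ axis needs >= 2 samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6 * dt[0]:
        raise InvalidInputError(f"{path}: Ψ axis grid is not evenly spaced")
    return PsiAxis(float(t[0]), float(dt[0]), df["psi_mpa"].to_numpy(float))


def write_psi_axis(axis: PsiAxis, path) -> None:
    pd.DataFrame({"time_s": axis.times, "psi_mpa": axis.psi}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_vessels(path) -> pd.DataFrame:
    """Per-vessel table: ``vessel_id, organ, area_um2, t_um, b_um, group_id``."""
    df = _read_csv(path, VESSEL_COLUMNS)
    if (df["area_um2"] <= 0).any():
        raise InvalidInputError(f"{path}: vessel areas must be positive")
    return df


def write_vessels(df: pd.DataFrame, path) -> None:
    df.loc[:, list(VESSEL_COLUMNS)].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_geometry(path, organ: str = "stem") -> SectionGeometry:
    """Section geometry table: ``organ, stem_area_mm2, parenchyma_area_mm2``."""
    df = _read_csv(path, ("organ", "stem_area_mm2", "parenchyma_area_mm2"))
    row = df[df["organ"] == organ]
    if row.empty:
        raise InvalidInputError(f"{path}: no geometry row for organ {organ!r}")
    return SectionGeometry(
        float(row["stem_area_mm2"].iloc[0]),
        float(row["parenchyma_area_mm2"].iloc[0]),
    )


def write_geometry(geometry: SectionGeometry, path, organ: str = "stem") -> None:
    pd.DataFrame(
        [{
            "organ": organ,
            "stem_area_mm2": geometry.stem_area_mm2,
            "parenchyma_area_mm2": geometry.parenchyma_area_mm2,
        }]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class ExperimentConfig:
    """One shoot's files plus every processing parameter of the pipeline."""

    cultivar: str = "Excalibur"
    shoot_id: str = "shoot-1"
    # input files (resolved relative to the config file when loaded from YAML)
    ae_events: str | None = None
    dendrometer: str | None = None
    psi_obs: str | None = None
    balance: str | None = None
    vessels: str | None = None
    geometry: str | None = None
    # instrument / processing parameters
    reference_diameter_mm: float = 2.5
    bin_s: float = 300.0
    activity_window_s: float = 900.0
    d3_window_s: float = 9000.0
    min_amplitude_dbae: float = 28.0
    band_khz: tuple[float, float] = (20.0, 1000.0)
    psi_grid_step: float = 0.01
    cwr_window: float = 0.10
    # simulation controls
    seed: int = 0
    duration_h: float = 30.0

    def __post_init__(self):
        for name in ("activity_window_s", "d3_window_s"):
            w = getattr(self, name)
            if w <= 0 or abs(w / self.bin_s - round(w / self.bin_s)) > 1e-9:
                raise InvalidInputError(
                    f"{name}={w} must be a positive multiple of bin_s={self.bin_s}"
                )
        if self.reference_diameter_mm <= 0:
            raise InvalidInputError("reference diameter must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "band_khz" in raw:
            raw["band_khz"] = tuple(raw["band_khz"])
        cfg = cls(**raw)
        for name in ("ae_events", "dendrometer", "psi_obs", "balance",
                     "vessels", "geometry"):
            value = getattr(cfg, name)
            if value is not None:
                setattr(cfg, name, str((path.parent / value).resolve()))
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["band_khz"] = list(self.band_khz)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
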