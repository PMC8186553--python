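#!/usr/bin/env python
"""Desorption curves and hydraulic capacitances per cultivar.

Gravimetric shoots carry no dendrometer, so each cultivar's balance traces
are mapped to Ψ through the mean Ψ axis of its paired acoustic shoots
(time-aligned at excision).  Two-breakpoint segmented fits locate the phase
boundaries (truncated at the cultivar AE_100, where the phase model ends)
and the phase slopes give C_el and C_inel, summarized as mean ± SE.
Writes results/dc_summary.csv.  Requires 01 (data) and 02 (Ψ axes).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from aehydro import io, pipeline, simulate
from aehydro.exceptions import AEHydroError
from aehydro.psi_axis import PsiAxis

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"
N_SHOOTS = 4


def mean_axis(folder: Path) -> PsiAxis:
    """Cultivar-mean Ψ(t) from the acoustic shoots' reconstructed axes."""
    axes = []
    for shoot in range(1, N_SHOOTS + 1):
        cfg = io.ExperimentConfig(shoot_id=f"shoot{shoot}")
        cfg.ae_events = str(folder / f"ae_events_shoot{shoot}.csv")
        cfg.dendrometer = str(folder / f"dendro_shoot{shoot}.csv")
        cfg.psi_obs = str(folder / f"psi_obs_shoot{shoot}.csv")
        axes.append(pipeline.run_vc(cfg).axis)
    n = min(len(a) for a in axes)
    return PsiAxis(0.0, axes[0].dt,
                   np.mean([a.psi[:n] for a in axes], axis=0))


def main():
    RESULTS.mkdir(exist_ok=True)
    vc_summary = pd.read_csv(RESULTS / "vc_summary.csv").set_index("cultivar")
    rows = []
    for cultivar in simulate.CULTIVAR_TABLE:
        folder = SCRATCH / cultivar.replace(" ", "_")
        if not folder.exists():
            raise SystemExit(f"{folder} missing - run 01_simulate.py first")
        axis = mean_axis(folder)
        ae100 = float(vc_summary.loc[cultivar, "ae100"])
        c_els, c_inels, bp1s, bp2s = [], [], [], []
        for shoot in range(1, N_SHOOTS + 1):
            cfg = io.ExperimentConfig(cultivar=cultivar, shoot_id=f"shoot{shoot}")
            cfg.balance = str(folder / f"mass_shoot{shoot}.csv")
            try:
                curve = pipeline.run_dc(cfg, ae100, axis=axis).curve
            except AEHydroError as exc:
                print(f"  {cultivar} shoot{shoot}: skipped ({exc})")
                continue
            c_els.append(curve.c_el)
            c_inels.append(curve.c_inel)
            bp1s.append(curve.bp1)
            bp2s.append(curve.bp2)

        def mse(v):
            return float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(len(v)))

        c_el, c_el_se = mse(c_els)
        c_inel, c_inel_se = mse(c_inels)
        rows.append({
            "cultivar": cultivar, "n_shoots": len(c_els),
            "bp1": np.mean(bp1s), "bp2": np.mean(bp2s), "ae100": ae100,
            "c_el": c_el, "c_el_se": c_el_se,
            "c_inel": c_inel, "c_inel_se": c_inel_se,
        })
        print(f"{cultivar}: C_el {c_el:.2f} ± {c_el_se:.2f}, "
              f"C_inel {c_inel:.2f} ± {c_inel_se:.2f} g MPa⁻¹ "
              f"(phases {np.mean(bp1s):.2f} / {np.mean(bp2s):.2f} / {ae100:.2f} MPa)")
    pd.DataFrame(rows).to_csv(RESULTS / "dc_summary.csv", index=False,
                              float_format="%.4g")


if __name__ == "__main__":
    main()
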