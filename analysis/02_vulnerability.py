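#!/usr/bin/env python
"""Acoustic vulnerability curves per cultivar.

Runs the full acoustic pipeline (filter, cumulate, endpoint, PLC,
stress–strain Ψ axis) on every simulated shoot, averages the four replicate
curves per cultivar, and summarizes AE_12/50/88/100 and t_100% as
mean ± SE.  Also regresses the Ψ at maximum acoustic activity on AE_50
across cultivars — on symmetric sigmoid curves the two coincide, so the
slope should be near 1.  Writes results/vc_summary.csv,
results/ae50_regression.json and the mean curves under results/curves/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from aehydro import io, pipeline, simulate, vulnerability

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"
N_SHOOTS = 4


def analyse_cultivar(cultivar: str):
    folder = SCRATCH / cultivar.replace(" ", "_")
    if not folder.exists():
        raise SystemExit(f"{folder} missing - run analysis/01_simulate.py first")
    results = []
    for shoot in range(1, N_SHOOTS + 1):
        tag = f"shoot{shoot}"
        cfg = io.ExperimentConfig(cultivar=cultivar, shoot_id=tag)
        cfg.ae_events = str(folder / f"ae_events_{tag}.csv")
        cfg.dendrometer = str(folder / f"dendro_{tag}.csv")
        cfg.psi_obs = str(folder / f"psi_obs_{tag}.csv")
        results.append(pipeline.run_vc(cfg))
    avg = vulnerability.average_curves([r.curve for r in results])
    return results, avg


def main():
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "curves").mkdir(exist_ok=True)
    rows, pairs = [], []
    for cultivar in simulate.CULTIVAR_TABLE:
        results, avg = analyse_cultivar(cultivar)
        m, se = avg.mean, avg.se
        rows.append({
            "cultivar": cultivar,
            "ae12": m.ae12, "ae12_se": se["ae12"],
            "ae50": m.ae50, "ae50_se": se["ae50"],
            "ae88": m.ae88, "ae88_se": se["ae88"],
            "ae100": m.ae100, "ae100_se": se["ae100"],
            "t100_h": m.t100, "t100_se": se["t100"],
        })
        pairs.append((m.ae50, float(np.mean(
            [r.curve.psi_at_max_activity for r in results]
        ))))
        pd.DataFrame({
            "psi_mpa": avg.psi_grid,
            "plc_mean": avg.plc_mean,
            "plc_se": avg.plc_se,
        }).to_csv(RESULTS / "curves" / f"vc_{cultivar.replace(' ', '_')}.csv",
                  index=False, float_format="%.6g")
        print(f"{cultivar}: AE_50 {m.ae50:.2f} ± {se['ae50']:.2f} MPa, "
              f"t_100% {m.t100:.1f} ± {se['t100']:.1f} h")

    pd.DataFrame(rows).to_csv(RESULTS / "vc_summary.csv", index=False,
                              float_format="%.4g")
    reg = vulnerability.ae50_activity_regression(pairs)
    (RESULTS / "ae50_regression.json").write_text(json.dumps({
        "slope": reg.slope, "intercept": reg.intercept, "r2": reg.r2,
        "n_cultivars": len(pairs),
    }, indent=2) + "\n")
    print(f"\nΨ_maxactivity = {reg.slope:.3f}·AE_50 + {reg.intercept:+.3f}, "
          f"R² = {reg.r2:.3f}")


if __name__ == "__main__":
    main()
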