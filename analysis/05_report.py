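#!/usr/bin/env python
"""Merge vulnerability, desorption and anatomy summaries into a ranking table.

Cultivars are ranked per parameter (1 = most drought-tolerant reading of
that parameter: most negative AE_50, longest t_100%, largest capacitances,
largest d_h).  The table makes the safety/efficiency contrast visible: a
cultivar can rank first on AE_50 yet last on capacitance.  Writes
results/ranking.csv.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"

RANK_DIRECTIONS = {
    "ae50": True,      # more negative = safer xylem
    "t100_h": False,   # longer survival = better
    "c_el": False,     # more stored water = better
    "c_inel": False,
    "d_h_um": False,   # wider vessels = more efficient
    "v_g": False,
}


def main():
    vc = pd.read_csv(RESULTS / "vc_summary.csv")
    dc = pd.read_csv(RESULTS / "dc_summary.csv")
    an = pd.read_csv(RESULTS / "anatomy_summary.csv")
    table = vc.merge(dc, on="cultivar").merge(an, on="cultivar")
    for col, ascending in RANK_DIRECTIONS.items():
        table[f"rank_{col}"] = table[col].rank(ascending=ascending).astype(int)
    table.to_csv(RESULTS / "ranking.csv", index=False, float_format="%.4g")
    cols = ["cultivar"] + [f"rank_{c}" for c in RANK_DIRECTIONS]
    print(table[cols].to_string(index=False))
    print("\nwrote", RESULTS / "ranking.csv")


if __name__ == "__main__":
    main()
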