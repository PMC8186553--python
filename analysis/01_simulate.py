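#!/usr/bin/env python
"""Generate the virtual bench-dehydration campaign.

Four replicate shoots per cultivar for five cereal cultivars, each
calibrated so its generator truth reproduces the cultivar's published
vulnerability thresholds, dehydration time and capacitances.  Every sensor
stream (AE events, dendrometer, balance, pressure chamber) is written as
CSV under scratch/simulated/, with the truth parameters alongside, so the
downstream analyses run from files exactly as they would on real exports.
"""

from pathlib import Path

from aehydro import io, pipeline, simulate

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "simulated"
N_SHOOTS = 4
BASE_SEED = 20_000


def main():
    for i, cultivar in enumerate(simulate.CULTIVAR_TABLE):
        t100 = simulate.CULTIVAR_TABLE[cultivar]["t100"]
        duration = round(t100 * 1.4, 1)
        out = SCRATCH / cultivar.replace(" ", "_")
        for shoot in range(N_SHOOTS):
            cfg = io.ExperimentConfig(
                cultivar=cultivar,
                shoot_id=f"shoot{shoot + 1}",
                seed=BASE_SEED + 100 * shoot + i,
                duration_h=duration,
            )
            exp = pipeline.run_simulate(cfg, out)
            print(f"{cultivar} shoot{shoot + 1}: {len(exp.events)} AE events "
                  f"over {duration} h -> {out}")
    print(f"\nAll streams under {SCRATCH}")


if __name__ == "__main__":
    main()
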