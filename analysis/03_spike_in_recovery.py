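"""Spike-in recovery under a multiplicative stage-loss model.

For each spiking concentration (1, 10, 100 tumour cells per 10^6 PBMCs) and
each processing scenario (lossless, and a two-stage lossy protocol), simulates
replicate experiments where every spiked cell survives each stage
independently, and tabulates recovery rates to results/spike_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import ctcpheno as cp

SCENARIOS = {
    "lossless": [1.0, 1.0],
    "two_stage_90pct": [0.9, 0.9],
    "harsh_processing": [0.7, 0.6],
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = []
    for s, (name, stages) in enumerate(SCENARIOS.items()):
        for c, conc in enumerate([1, 10, 100]):
            rates = cp.simulate_spike_in(
                conc, stages, n_replicates=10, seed=args.seed + 10 * s + c
            )
            rows.append(
                {
                    "scenario": name,
                    "stage_retention": "x".join(map(str, stages)),
                    "expected_recovery_pct": round(100 * float(np.prod(stages)), 1),
                    "cells_per_1e6_pbmc": conc,
                    "mean_recovery_pct": round(100 * float(rates.mean()), 1),
                    "sd_recovery_pct": round(100 * float(rates.std(ddof=1)), 1),
                }
            )
    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "spike_recovery.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nMean recovery tracks the product of stage retentions; replicate "
        "spread shrinks with concentration (binomial)."
    )


if __name__ == "__main__":
    main()
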