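#!/usr/bin/env python
"""Parameter recovery of the standardisation machinery on synthetic data.

Generates region x ward systems with known efficiency multipliers (true
PI), complexity tilts (known closed-form CMI) and a target occupancy, then
runs the full benchmark/indicator pipeline and compares estimates with
truth.  Finding: with 50,000 discharges/region the PI recovers the
efficiency multiplier to ~0.3% per seed (<0.1% averaged over 20 seeds),
the CMI matches its closed form, and realised BOR sits just below target
(ceiling bed-sizing).  Writes the recovery table under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bedmix import SyntheticParams, recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

EFFS = (0.85, 0.95, 1.05, 1.15)  # discharge-weighted mean efficiency = 1
TILTS = (0.0, 0.3, 0.6, 0.9)


def main(seed: int = 1) -> None:
    reports = []
    for s in range(seed, seed + 20):
        rep = recovery_experiment(
            SyntheticParams(
                n_regions=4,
                efficiency=EFFS,
                tilt=TILTS,
                discharges_per_region=50_000,
                target_bor=79.0,
                seed=s,
            )
        )
        rep["seed"] = s
        reports.append(rep)
    full = pd.concat(reports, ignore_index=True)
    full.to_csv(OUT / "synthetic_recovery.csv", index=False)

    summary = full.groupby("region").agg(
        e_true=("efficiency_true", "first"),
        pi_mean=("pi_hat", "mean"),
        pi_expected=("pi_expected", "first"),
        cmi_mean=("cmi_hat", "mean"),
        cmi_expected=("cmi_expected", "first"),
        bor_mean=("bor_hat", "mean"),
    )
    print(summary.round(4).to_string())
    rel = np.abs(summary["pi_mean"] - summary["pi_expected"]) / summary["pi_expected"]
    print(f"max |PI error| over 20-seed means: {rel.max():.2%}")
    print("-> synthetic_recovery.csv")


if __name__ == "__main__":
    main()
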