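#!/usr/bin/env python
"""Invert the drop-shape model for tension over the puddle-geometry table.

Reads results/synthetic/puddle_geometry.csv, estimates tension per sample
from the yolk index, and reports group means against the generating truth
and the flattened/round tension ratio.  Writes
results/puddle_inversion.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vitellometrics import invert_tension
from vitellometrics.io import read_puddle_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    table = read_puddle_table(RESULTS / "synthetic" / "puddle_geometry.csv")
    truth = pd.read_csv(RESULTS / "synthetic" / "puddle_truth.csv").set_index("day")

    gammas, yis = [], []
    for row in table.itertuples():
        yi = row.height_mm / row.diameter_mm
        yis.append(yi)
        gammas.append(
            invert_tension(yi, row.volume_ml * 1e-6, row.density_g_per_cm3 * 1e3)
        )
    table["yolk_index"] = yis
    table["gamma_N_per_m"] = gammas
    table.to_csv(RESULTS / "puddle_inversion.csv", index=False)

    print("tension recovered from noisy puddle geometry (mean +/- SD vs truth):")
    for day, grp in table.groupby("day"):
        g = grp.gamma_N_per_m
        print(
            f"  {day}: {g.mean():.3f} +/- {g.std(ddof=1):.3f} N/m "
            f"(truth {truth.loc[day, 'gamma_true_N_per_m']:.3f}, n={len(g)})"
        )
    means = table.groupby("day").gamma_N_per_m.mean()
    days = sorted(means.index)
    if len(days) >= 2:
        ratio = means[days[-1]] / means[days[0]]
        print(
            f"tension retained {days[0]} -> {days[-1]}: {100 * ratio:.1f}% "
            f"(all estimates within the 0.1-1 N/m order of magnitude: "
            f"{bool(((table.gamma_N_per_m >= 0.1) & (table.gamma_N_per_m <= 1.0)).all())})"
        )


if __name__ == "__main__":
    main()
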