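#!/usr/bin/env python
"""Extract linear-phase stiffness slopes from the synthetic probe traces.

Reads results/synthetic/probe_traces/, runs baseline correction, 1-Hz
averaging, QC and windowed line fitting, and writes results/stiffness.csv;
prints group means against generator truth and the group comparison.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vitellometrics import (
    baseline_correct,
    downsample_1hz,
    linear_phase_slope,
    qc_trace,
    two_sample_test,
)
from vitellometrics.io import read_probe_trace

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    truth = pd.read_csv(RESULTS / "synthetic" / "probe_truth.csv").set_index(
        "sample_id"
    )
    rows = []
    for path in sorted((RESULTS / "synthetic" / "probe_traces").glob("*.csv")):
        trace = downsample_1hz(baseline_correct(read_probe_trace(path)))
        flag = qc_trace(trace)
        slope = np.nan
        if flag == "ok":
            slope = linear_phase_slope(trace).slope_mN_per_s
        rows.append(
            {
                "sample_id": path.stem,
                "day": truth.loc[path.stem, "day"],
                "slope_mN_per_s": slope,
                "qc": flag,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "stiffness.csv", index=False)

    print("probe stiffness recovery (mean vs truth):")
    for day, grp in out[out.qc == "ok"].groupby("day"):
        t = truth[truth.day == day].slope_mN_per_s.iloc[0]
        print(
            f"  {day}: {grp.slope_mN_per_s.mean():.4f} +/- "
            f"{grp.slope_mN_per_s.std(ddof=1):.4f} mN/s (truth {t:.3f}, n={len(grp)})"
        )
    ok = out[out.qc == "ok"]
    days = sorted(ok.day.unique())
    if len(days) == 2:
        res = two_sample_test(ok, "slope_mN_per_s", days[0], days[1])
        print(f"Welch t-test {days[0]} vs {days[1]}: t={res.t:.2f}, p={res.p:.2g}")


if __name__ == "__main__":
    main()
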