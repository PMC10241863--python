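#!/usr/bin/env python
"""Assemble the summary panel: per-group mean +/- SD and group tests.

Reads the tidy metric tables written by the earlier stages from results/
and writes results/report/{summary.csv,tests.csv,report.json}.
"""

from pathlib import Path

import pandas as pd

from vitellometrics import build_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    report = build_report(RESULTS, RESULTS / "report")
    summary = pd.DataFrame(report["summary"])
    print(f"{report['n_metrics']} metrics summarized, "
          f"{report['n_comparisons']} pairwise comparisons (no correction):")
    if len(summary):
        print(summary.to_string(index=False))
    tests = pd.DataFrame(report["tests"])
    if len(tests):
        print("\ngroup tests:")
        print(tests.to_string(index=False))


if __name__ == "__main__":
    main()
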