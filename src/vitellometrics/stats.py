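"""Group comparisons and summary-report assembly.

The study design compares a metric (tension, stiffness slope, speed, fibre
density) between day-groups of distinct samples: two-tailed t-tests for
pairs and one-way ANOVA for multi-group panels.  Welch's unequal-variance
t-test is the default (group SDs typically differ visibly); a pooled
equal-variance mode is available.  No multiple-testing correction is
applied; the report records the number of comparisons instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = [
    "TTestResult",
    "AnovaResult",
    "two_sample_test",
    "one_way_anova",
    "build_report",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    equal_var: bool


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def _group_values(table: pd.DataFrame, metric: str, group_col: str, group):
    vals = table.loc[table[group_col] == group, metric].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"missing/non-finite {metric!r} values in group {group!r}")
    return vals


def two_sample_test(
    table: pd.DataFrame,
    metric: str,
    group_a,
    group_b,
    group_col: str = "day",
    equal_var: bool = False,
) -> TTestResult:
    """Two-tailed two-sample t-test between two groups of a tidy table.

    ``equal_var=False`` (default) runs Welch's test with Satterthwaite
    degrees of freedom; ``equal_var=True`` the pooled-variance test.
    """
    a = _group_values(table, metric, group_col, group_a)
    b = _group_values(table, metric, group_col, group_b)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 values per group for a t-test")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=a.size,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=b.size,
        equal_var=equal_var,
    )


def one_way_anova(
    table: pd.DataFrame, metric: str, group_col: str = "day"
) -> AnovaResult:
    """Standard one-way ANOVA across all groups of a tidy table.

    When every group is an identical constant the F statistic is undefined
    (0/0); the result is returned with ``degenerate=True`` and NaN F/p.
    """
    groups = [
        _group_values(table, metric, group_col, g)
        for g in pd.unique(table[group_col])
    ]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InsufficientDataError("need >= 2 groups with >= 2 values each")
    df_b = len(groups) - 1
    df_w = sum(g.size for g in groups) - len(groups)
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return AnovaResult(
            f=float("nan"), df_between=df_b, df_within=df_w, p=float("nan"),
            degenerate=True,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.f_oneway(*groups)
    return AnovaResult(
        f=float(res.statistic), df_between=df_b, df_within=df_w,
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

#: result files understood by build_report: filename -> (group col, metrics)
_REPORT_INPUTS = {
    "scale_tension.csv": ("day", ["gamma_native_N_per_m", "gamma_max_N_per_m"]),
    "stiffness.csv": ("day", ["slope_mN_per_s"]),
    "puddle_inversion.csv": ("day", ["gamma_N_per_m", "yolk_index"]),
    "morphometry.csv": (
        "day",
        ["elongation_um_h", "convergence_um_h", "segmentation_per_h"],
    ),
    "fibre_density.csv": ("day", ["density"]),
}

_SUMMARY_COLUMNS = ["metric", "group", "n", "mean", "sd"]
_TEST_COLUMNS = [
    "metric", "group_a", "group_b", "t", "df", "p", "mean_a", "mean_b",
]


def build_report(results_dir, out_dir=None) -> dict:
    """Assemble per-group mean +/- SD summaries and pairwise tests.

    Scans ``results_dir`` for the tidy per-module CSVs produced by the
    analysis drivers (see ``_REPORT_INPUTS``), and writes ``summary.csv``
    (metric x group mean/SD panel), ``tests.csv`` (all pairwise Welch
    t-tests plus per-metric ANOVA p when >2 groups) and ``report.json`` to
    ``out_dir`` (defaults to ``results_dir``).  An empty directory yields
    empty tables with the full schema.  Re-running is idempotent.
    """
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir is not None else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    summary_rows, test_rows, anova_rows = [], [], []
    for fname, (group_col, metrics) in _REPORT_INPUTS.items():
        path = results_dir / fname
        if not path.exists():
            continue
        table = pd.read_csv(path)
        groups = list(pd.unique(table[group_col]))
        for metric in metrics:
            if metric not in table.columns:
                continue
            for g in groups:
                vals = table.loc[table[group_col] == g, metric].dropna()
                summary_rows.append(
                    {
                        "metric": metric,
                        "group": g,
                        "n": int(vals.size),
                        "mean": float(vals.mean()) if vals.size else float("nan"),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    }
                )
            sub = table.dropna(subset=[metric])
            counts = sub.groupby(group_col)[metric].count()
            usable = [g for g in groups if counts.get(g, 0) >= 2]
            for i, ga in enumerate(usable):
                for gb in usable[i + 1 :]:
                    import warnings

                    with warnings.catch_warnings():
                        # zero-variance metrics (e.g. noise-free synthetic
                        # series) trip scipy's precision warning; the inf
                        # statistic is the honest answer there
                        warnings.simplefilter("ignore", RuntimeWarning)
                        r = two_sample_test(sub, metric, ga, gb, group_col)
                    test_rows.append(
                        {
                            "metric": metric,
                            "group_a": ga,
                            "group_b": gb,
                            "t": r.t,
                            "df": r.df,
                            "p": r.p,
                            "mean_a": r.mean_a,
                            "mean_b": r.mean_b,
                        }
                    )
            if len(usable) > 2:
                a = one_way_anova(sub[sub[group_col].isin(usable)], metric, group_col)
                anova_rows.append(
                    {"metric": metric, "f": a.f, "p": a.p,
                     "df_between": a.df_between, "df_within": a.df_within}
                )

    summary = pd.DataFrame(summary_rows, columns=_SUMMARY_COLUMNS)
    tests = pd.DataFrame(test_rows, columns=_TEST_COLUMNS)
    summary.to_csv(out_dir / "summary.csv", index=False)
    tests.to_csv(out_dir / "tests.csv", index=False)
    report = {
        "n_metrics": int(summary["metric"].nunique()) if len(summary) else 0,
        "n_comparisons": len(tests),
        "multiple_testing_correction": "none",
        "anova": anova_rows,
        "summary": summary.to_dict(orient="records"),
        "tests": tests.to_dict(orient="records"),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
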