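"""Group tests against explicit sums-of-squares oracles, and calibration."""

import numpy as np
import pandas as pd
import pytest

from vitellometrics import (
    InsufficientDataError,
    build_report,
    one_way_anova,
    two_sample_test,
)


def table(groups):
    rows = [
        {"day": name, "value": v} for name, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


def pooled_t_oracle(a, b):
    """Equal-variance two-sample t by explicit arithmetic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, na + nb - 2


def welch_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def anova_oracle(groups):
    """One-way ANOVA F by explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


class TestTwoSampleTest:
    def test_identical_groups_null(self):
        res = two_sample_test(
            table({"A": [1, 2, 3], "B": [1, 2, 3]}), "value", "A", "B"
        )
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_pooled_variance_hand_value(self):
        """{1,2,3} vs {4,5,6}: t = -3.674, df = 4, p ~ 0.0214."""
        res = two_sample_test(
            table({"A": [1, 2, 3], "B": [4, 5, 6]}), "value", "A", "B",
            equal_var=True,
        )
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0214, abs=5e-4)

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_explicit_oracle(self, equal_var, rng):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.5, 2.0, 12)
        res = two_sample_test(
            table({"A": a, "B": b}), "value", "A", "B", equal_var=equal_var
        )
        t, df = pooled_t_oracle(a, b) if equal_var else welch_t_oracle(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)

    def test_reports_group_summaries(self):
        res = two_sample_test(
            table({"A": [1, 2, 3], "B": [4, 5, 6]}), "value", "A", "B"
        )
        assert res.mean_a == 2.0 and res.mean_b == 5.0
        assert res.sd_a == pytest.approx(1.0)
        assert res.n_a == res.n_b == 3

    def test_singleton_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_sample_test(table({"A": [1.0], "B": [1, 2]}), "value", "A", "B")

    def test_type_i_error_calibrated(self, rng):
        """Welch test under a simulated null keeps ~5% false positives."""
        n_rep, n = 1000, 10
        a = rng.normal(size=(n, n_rep))
        b = rng.normal(size=(n, n_rep))
        from scipy.stats import ttest_ind

        p = ttest_ind(a, b, equal_var=False, axis=0).pvalue
        rate = float((p < 0.05).mean())
        # binomial 2 SE around 0.05 at 1000 reps
        assert abs(rate - 0.05) <= 2.0 * np.sqrt(0.05 * 0.95 / n_rep)


class TestAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        groups = [rng.normal(m, 1.0, n) for m, n in [(0, 6), (0.5, 8), (1.0, 7)]]
        res = one_way_anova(
            table({f"G{i}": g for i, g in enumerate(groups)}), "value"
        )
        f, df_b, df_w = anova_oracle(groups)
        assert res.f == pytest.approx(f, abs=1e-10)
        assert (res.df_between, res.df_within) == (df_b, df_w)

    def test_textbook_three_groups(self):
        """Hand-computed example: groups {1,2,3}, {2,3,4}, {4,5,6}."""
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([4.0, 5, 6])]
        f, df_b, df_w = anova_oracle(groups)
        res = one_way_anova(
            table({"A": groups[0], "B": groups[1], "C": groups[2]}), "value"
        )
        assert f == pytest.approx(7.0, abs=1e-10)  # SSB/2 = 7, SSW/6 = 1
        assert res.f == pytest.approx(f, abs=1e-10)

    def test_identical_constant_groups_degenerate(self):
        res = one_way_anova(
            table({"A": [2.0, 2.0], "B": [2.0, 2.0]}), "value"
        )
        assert res.degenerate and np.isnan(res.f)

    def test_null_type_i_error(self, rng):
        from scipy.stats import f_oneway

        n_rep = 1000
        groups = [rng.normal(size=(8, n_rep)) for _ in range(3)]
        p = f_oneway(*groups, axis=0).pvalue
        rate = float((p < 0.05).mean())
        assert abs(rate - 0.05) <= 2.0 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_too_few_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova(table({"A": [1, 2, 3]}), "value")


class TestBuildReport:
    def test_empty_dir_keeps_schema(self, tmp_path):
        report = build_report(tmp_path)
        assert report["n_metrics"] == 0
        summary = pd.read_csv(tmp_path / "summary.csv")
        assert list(summary.columns) == ["metric", "group", "n", "mean", "sd"]

    def test_row_count_is_metrics_times_groups(self, tmp_path):
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "day": ["D0"] * 4 + ["D2"] * 4,
                "gamma_native_N_per_m": np.r_[np.full(4, 0.6), np.full(4, 0.25)]
                + np.linspace(0, 0.01, 8),
                "gamma_max_N_per_m": np.r_[np.full(4, 2.2), np.full(4, 1.0)]
                + np.linspace(0, 0.01, 8),
            }
        ).to_csv(tmp_path / "scale_tension.csv", index=False)
        report = build_report(tmp_path)
        summary = pd.read_csv(tmp_path / "summary.csv")
        assert len(summary) == 2 * 2  # two metrics x two groups
        assert report["n_comparisons"] == 2

    def test_rerun_idempotent(self, tmp_path):
        pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "day": ["D0", "D0", "D2", "D2"],
                "slope_mN_per_s": [0.08, 0.07, 0.03, 0.04],
            }
        ).to_csv(tmp_path / "stiffness.csv", index=False)
        first = build_report(tmp_path)
        second = build_report(tmp_path)
        assert first == second
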