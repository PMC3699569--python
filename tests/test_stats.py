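import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from inflammode.exceptions import InvalidInputError
from inflammode.stats import (
    anova_two_way_from_cells,
    fold_change_contrast,
    holm_sidak,
    t_from_replicates,
    t_from_summary,
)
from inflammode.synthetic import TimeCourseDataset


class TestTFromSummary:
    def test_identical_groups_give_t0_p1(self):
        res = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_welch_formula_and_quadrature_oracle(self):
        """|t| for (1.2±0.2) vs (2.8±0.3), n=16 each, and its p-value
        verified against direct numerical integration of the t density."""
        res = t_from_summary(1.2, 0.2, 16, 2.8, 0.3, 16, method="welch")
        assert abs(res.t) == pytest.approx(4.438, abs=1e-3)
        v1, v2 = 0.04, 0.09
        df_expected = (v1 + v2) ** 2 / (v1 ** 2 / 15 + v2 ** 2 / 15)
        assert res.df == pytest.approx(df_expected)

        from scipy.integrate import quad

        def t_pdf(x, df):
            c = math.gamma((df + 1) / 2) / (
                math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = quad(t_pdf, abs(res.t), np.inf, args=(res.df,))
        assert res.p == pytest.approx(2 * tail, rel=1e-8)

    def test_agrees_with_scipy_from_stats(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1, m2 = rng.normal(size=2) * 10
            s1, s2 = rng.uniform(0.5, 3.0, size=2)
            n1, n2 = rng.integers(3, 30, size=2)
            for method, equal_var in (("welch", False), ("pooled", True)):
                mine = t_from_summary(m1, s1, n1, m2, s2, n2, method=method)
                ref = sps.ttest_ind_from_stats(
                    m1, s1 * math.sqrt(n1), n1,
                    m2, s2 * math.sqrt(n2), n2, equal_var=equal_var)
                assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
                assert mine.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_one_sample_degeneracy(self):
        """A zero-variance group becomes the reference constant."""
        res = t_from_summary(0.0, 0.0, 16, 20.2, 3.5, 16)
        assert res.method == "one-sample-degenerate"
        assert res.df == 15
        assert res.t == pytest.approx(-20.2 / 3.5)
        assert res.p < 0.001

    def test_double_degenerate(self):
        with pytest.warns(UserWarning):
            eq = t_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert eq.p == 1.0
        with pytest.warns(UserWarning):
            ne = t_from_summary(3.0, 0.0, 5, 4.0, 0.0, 5)
        assert ne.p == 0.0

    def test_summary_equals_raw_computation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x1 = rng.normal(10, 2, size=12)
            x2 = rng.normal(11, 3, size=9)
            raw = t_from_replicates(x1, x2)
            summ = t_from_summary(
                x1.mean(), x1.std(ddof=1) / math.sqrt(len(x1)), len(x1),
                x2.mean(), x2.std(ddof=1) / math.sqrt(len(x2)), len(x2))
            assert raw.t == pytest.approx(summ.t, abs=1e-10)
            assert raw.p == pytest.approx(summ.p, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            t_from_summary(1.0, -0.1, 5, 2.0, 0.1, 5)
        with pytest.raises(InvalidInputError):
            t_from_summary(1.0, 0.1, 0, 2.0, 0.1, 5)


def _cells_from_raw(df, factor_a, factor_b):
    rows = []
    for (a, b), grp in df.groupby([factor_a, factor_b]):
        v = grp["y"].to_numpy(dtype=float)
        rows.append({factor_a: a, factor_b: b, "mean": v.mean(),
                     "sem": v.std(ddof=1) / math.sqrt(len(v)), "n": len(v)})
    return pd.DataFrame(rows)


class TestAnova:
    def test_equal_cell_means_give_zero_f(self):
        cells = pd.DataFrame({
            "age": ["y", "y", "o", "o"], "time": [0, 1, 0, 1],
            "mean": [5.0] * 4, "sem": [0.5] * 4, "n": [4] * 4,
        })
        res = anova_two_way_from_cells(cells, "age", "time")
        for effect in ("age", "time", "age:time"):
            assert res.effect(effect)["F"] == pytest.approx(0.0, abs=1e-12)
            assert res.effect(effect)["p"] == pytest.approx(1.0)

    def test_matches_statsmodels_on_raw_data(self):
        """Summary-level ANOVA equals the raw-replicate ANOVA exactly."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        rows = []
        for a in ("young", "aged"):
            for b in ("t0", "t1", "t2"):
                shift = (a == "aged") * 2.0 + (b == "t2") * 1.5
                for v in rng.normal(10 + shift, 1.0, size=6):
                    rows.append({"A": a, "B": b, "y": v})
        df = pd.DataFrame(rows)
        mine = anova_two_way_from_cells(_cells_from_raw(df, "A", "B"), "A", "B")
        fit = ols("y ~ C(A) * C(B)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for effect, label in (("A", "C(A)"), ("B", "C(B)"),
                              ("A:B", "C(A):C(B)")):
            assert mine.effect(effect)["F"] == pytest.approx(
                ref.loc[label, "F"], abs=1e-8)
            assert mine.effect(effect)["p"] == pytest.approx(
                ref.loc[label, "PR(>F)"], abs=1e-10)

    def test_null_interaction_p_is_well_behaved(self):
        """Additive truth: the interaction test rarely fires at alpha=0.01."""
        rng = np.random.default_rng(11)
        n_reps, hits = 100, 0
        for _ in range(n_reps):
            rows = []
            for a in (0, 1):
                for b in (0, 1):
                    y = rng.normal(10 + 2 * a + 1 * b, 1.0, size=1000)
                    rows.append({"A": a, "B": b, "mean": y.mean(),
                                 "sem": y.std(ddof=1) / math.sqrt(len(y)),
                                 "n": len(y)})
            res = anova_two_way_from_cells(pd.DataFrame(rows), "A", "B")
            hits += res.effect("A:B")["p"] > 0.01
        assert hits >= 98

    def test_incomplete_grid_rejected(self):
        cells = pd.DataFrame({
            "age": ["y", "y", "o"], "time": [0, 1, 0],
            "mean": [1.0, 2.0, 3.0], "sem": [0.1] * 3, "n": [4] * 3,
        })
        with pytest.raises(InvalidInputError, match="missing cells"):
            anova_two_way_from_cells(cells, "age", "time")


class TestHolmSidak:
    def test_worked_example(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99 ** 2)
        assert adj[1] == pytest.approx(0.04)

    def test_single_and_extremes(self):
        assert holm_sidak([0.2]) == pytest.approx([0.2])
        assert holm_sidak([0.0, 0.0]) == pytest.approx([0.0, 0.0])
        assert holm_sidak([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 12))
            mine = holm_sidak(p)
            _, ref, _, _ = multipletests(p, method="holm-sidak")
            assert np.allclose(mine, ref, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_adjustment_never_decreases_p(self, pvals):
        adj = holm_sidak(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()


def _fold_dataset(rng, young_induction, aged_induction, n=16, cv=0.2,
                  saline_mean=10.0):
    sigma = math.sqrt(math.log(1 + cv * cv))
    rows = []
    for age, induction in (("young", young_induction),
                           ("middle-aged", aged_induction)):
        for trt, level in (("saline", saline_mean),
                           ("LPS", saline_mean * induction)):
            vals = level * np.exp(sigma * rng.standard_normal(n))
            for i, v in enumerate(vals, 1):
                rows.append({"age": age, "treatment": trt, "analyte": "IL-6",
                             "time_min": 90.0, "replicate": i, "value": v})
    return TimeCourseDataset(pd.DataFrame(rows))


class TestFoldChange:
    def test_identical_induction_gives_unit_folds(self):
        rows = []
        for age in ("young", "middle-aged"):
            for trt in ("saline", "LPS"):
                for i in range(1, 5):
                    rows.append({"age": age, "treatment": trt,
                                 "analyte": "IL-6", "time_min": 90.0,
                                 "replicate": i, "value": 10.0})
        table = fold_change_contrast(TimeCourseDataset(pd.DataFrame(rows)))
        row = table.iloc[0]
        assert row["fold_mean_young"] == pytest.approx(1.0)
        assert row["fold_mean_middle-aged"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_constructed_effect_is_detected(self):
        """10x vs 3x induction at n=16, CV 0.2: young folds win at alpha=.05."""
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(20):
            ds = _fold_dataset(rng, young_induction=10.0, aged_induction=3.0)
            row = fold_change_contrast(ds).iloc[0]
            if row["p"] < 0.05 and row["fold_mean_young"] > row["fold_mean_middle-aged"]:
                hits += 1
        assert hits >= 18

    def test_zero_saline_mean_reported_missing(self):
        rows = []
        for age in ("young", "middle-aged"):
            for trt, v in (("saline", 0.0), ("LPS", 50.0)):
                for i in range(1, 5):
                    rows.append({"age": age, "treatment": trt,
                                 "analyte": "TNF-a", "time_min": 90.0,
                                 "replicate": i, "value": v})
        table = fold_change_contrast(TimeCourseDataset(pd.DataFrame(rows)))
        row = table.iloc[0]
        assert math.isnan(row["p"])
        assert "zero saline mean" in row["reason"]

    def test_missing_saline_arm_rejected(self):
        rows = [{"age": a, "treatment": "LPS", "analyte": "IL-6",
                 "time_min": 90.0, "replicate": i, "value": 5.0}
                for a in ("young", "middle-aged") for i in range(1, 5)]
        with pytest.raises(InvalidInputError):
            fold_change_contrast(TimeCourseDataset(pd.DataFrame(rows)))


def test_welch_null_pvalues_are_uniform():
    """Type-I calibration: p under the null is ~Uniform(0,1) (KS < 0.1)."""
    rng = np.random.default_rng(23)
    pvals = []
    for _ in range(1000):
        x1 = rng.normal(0, 1, size=8)
        x2 = rng.normal(0, 1, size=8)
        pvals.append(t_from_replicates(x1, x2).p)
    ks = sps.kstest(pvals, "uniform").statistic
    assert ks < 0.1
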