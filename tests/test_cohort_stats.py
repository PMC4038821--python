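"""Correlation, regression, above-line contingency and grade comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prolifmark.cohort_stats import (
    ContingencyTable2x2,
    classify_above_line,
    correlation_matrix,
    fisher_exact_2x2,
    grade_summary,
    ols_fit,
    pearson_r,
    two_sample_t,
)
from prolifmark.errors import InvalidParameterError, UndefinedCorrelationError


def make_table(rows):
    return pd.DataFrame(rows, columns=["tumor_id", "grade", "mib1_per_field",
                                       "phh3_per_field", "mitoses_per_10hpf", "iod"])


class TestPearson:
    def test_perfect_affine_correlations(self):
        x = np.arange(1.0, 11.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert pearson_r(3 * x + 5, y) == pytest.approx(pearson_r(x, y), rel=1e-9)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        table = make_table([
            (f"T{i}", 1 + i % 3, *rng.uniform(1, 100, 4)) for i in range(20)
        ])
        corr = correlation_matrix(table)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr.values, corr.values.T)


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 120, 30)
        fit = ols_fit(x, 16.7 * x + 258.0)
        assert fit.slope == pytest.approx(16.7)
        assert fit.intercept == pytest.approx(258.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_slope_matches_normal_equations(self, rng):
        x = rng.uniform(0, 50, 40)
        y = 3 * x + rng.normal(0, 5, 40)
        fit = ols_fit(x, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(InvalidParameterError):
            ols_fit([2, 2, 2], [1, 2, 3])


class TestAboveLine:
    def test_on_line_counts_as_not_above(self):
        table = make_table([
            ("T0", 1, 258.0, 0.0, 1, 1.0),    # exactly on y = 16.7x + 258
            ("T1", 3, 300.0, 0.0, 1, 1.0),    # above
            ("T2", 3, 100.0, 0.0, 1, 1.0),    # below
        ])
        from prolifmark.cohort_stats import RegressionFit
        fit = RegressionFit(slope=16.7, intercept=258.0, pearson_r=1.0)
        above, ct = classify_above_line(table, fit)
        assert above.tolist() == [False, True, False]
        assert (ct.a, ct.b, ct.c, ct.d) == (0, 1, 1, 1)

    def test_classification_equals_residual_sign(self, rng):
        x = rng.uniform(0, 30, 25)
        y = 10 * x + rng.normal(0, 40, 25)
        table = make_table([
            (f"T{i}", 1 + i % 3, y[i], x[i], 1, 1.0) for i in range(25)
        ])
        fit = ols_fit(x, y)
        above, _ = classify_above_line(table, fit)
        residuals = y - fit.predict(x)
        assert (above.to_numpy() == (residuals > 0)).all()

    def test_reported_cohort_contingency(self):
        # above-line by grade 1/8, 5/21, 11/20 pools to (6, 23, 11, 9)
        rows = []
        i = 0
        for grade, n, k in ((1, 8, 1), (2, 21, 5), (3, 20, 11)):
            for j in range(n):
                above = j < k
                rows.append((f"T{i}", grade, 300.0 if above else 100.0, 0.0, 1, 1.0))
                i += 1
        table = make_table(rows)
        from prolifmark.cohort_stats import RegressionFit
        fit = RegressionFit(slope=16.7, intercept=258.0, pearson_r=1.0)
        _, ct = classify_above_line(table, fit)
        assert (ct.a, ct.b, ct.c, ct.d) == (6, 23, 11, 9)


def brute_force_fisher(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(aa):
        bb, cc, dd = row1 - aa, col1 - aa, n - row1 - col1 + aa
        if min(bb, cc, dd) < 0:
            return None
        return (math.comb(row1, aa) * math.comb(n - row1, cc)) / math.comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(0, min(row1, col1) + 1):
        p = prob(aa)
        if p is not None and p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_reported_above_line_table(self):
        p = fisher_exact_2x2(ContingencyTable2x2(6, 23, 11, 9))
        assert round(p, 3) == 0.017

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_brute_force_enumeration(self):
        # all 2x2 tables with total <= 14 against the factorial oracle
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d == 0:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                assert fisher_exact_2x2(t) == 1.0
            else:
                assert fisher_exact_2x2(t) == pytest.approx(
                    brute_force_fisher(a, b, c, d), rel=1e-9)

    def test_agrees_with_scipy(self):
        for table in [(6, 23, 11, 9), (2, 10, 8, 3), (1, 1, 9, 12)]:
            p = fisher_exact_2x2(ContingencyTable2x2(*table))
            p_scipy = stats.fisher_exact(np.array(table).reshape(2, 2)).pvalue
            assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_symmetric_under_row_and_column_swap(self):
        t = ContingencyTable2x2(3, 9, 7, 2)
        swapped = ContingencyTable2x2(2, 7, 9, 3)  # both rows and columns swapped
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped))


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            two_sample_t([2.0, 2.0], [5.0, 5.0])

    def test_matches_textbook_pooled_formula(self):
        x = np.array([4.0, 6.0, 5.0])
        y = np.array([8.0, 9.0, 10.0])
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / 4
        t_expected = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        t, p = two_sample_t(x, y)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)


class TestGradeSummary:
    def test_hand_table(self):
        table = make_table([
            ("T0", 1, 10.0, 1.0, 2, 100.0),
            ("T1", 1, 20.0, 3.0, 4, 200.0),
            ("T2", 3, 50.0, 5.0, 6, 300.0),
            ("T3", 3, 70.0, 7.0, 8, 500.0),
        ])
        summary = grade_summary(table)
        assert summary.loc["1", "mib1_per_field_mean"] == 15.0
        assert summary.loc["1", "mib1_per_field_sd"] == pytest.approx(np.std([10, 20], ddof=1))
        assert summary.loc["3", "iod_mean"] == 400.0
        assert summary.loc["all", "mib1_per_field_mean"] == 37.5

    def test_single_tumor_grade_has_missing_sd(self):
        table = make_table([
            ("T0", 1, 10.0, 1.0, 2, 100.0),
            ("T1", 3, 50.0, 5.0, 6, 300.0),
            ("T2", 3, 70.0, 7.0, 8, 500.0),
        ])
        summary = grade_summary(table)
        assert np.isnan(summary.loc["1", "mib1_per_field_sd"])
        assert not np.isnan(summary.loc["3", "mib1_per_field_sd"])

    def test_overall_mean_is_weighted_grade_mean(self, rng):
        table = make_table([
            (f"T{i}", 1 + i % 3, *rng.uniform(1, 100, 4)) for i in range(15)
        ])
        summary = grade_summary(table)
        weighted = sum(summary.loc[str(g), "iod_mean"] * summary.loc[str(g), "n"]
                       for g in (1, 2, 3)) / 15
        assert summary.loc["all", "iod_mean"] == pytest.approx(weighted)
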