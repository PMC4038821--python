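"""Cohort-level statistics: correlations, regression, contingency and grade tests.

Operates on a cohort table with one row per tumor and the four measured
variables (MIB-1/field, PhH3/field, mitoses/10 HPF, nuclear IOD) plus grade.
The above-line analysis asks whether high-grade tumors sit disproportionately
above the MIB-1-on-PhH3 regression line, i.e. carry more MIB-1 per unit PhH3
— the cohort-level signature of interphase lengthening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from prolifmark.errors import InvalidParameterError, UndefinedCorrelationError

__all__ = [
    "MARKER_VARIABLES",
    "RegressionFit",
    "ContingencyTable2x2",
    "pearson_r",
    "correlation_matrix",
    "ols_fit",
    "classify_above_line",
    "fisher_exact_2x2",
    "two_sample_t",
    "grade_summary",
]

MARKER_VARIABLES = ("mitoses_per_10hpf", "mib1_per_field", "phh3_per_field", "iod")


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares line y = slope * x + intercept with Pearson r."""

    slope: float
    intercept: float
    pearson_r: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: grade group (1-2 pooled, 3); columns: (above line, not above)."""

    a: int  # low grade, above
    b: int  # low grade, not above
    c: int  # grade 3, above
    d: int  # grade 3, not above

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in vals) or sum(vals) == 0:
            raise InvalidParameterError("cell counts must be >= 0 with a positive total")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises for constant vectors or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise InvalidParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def correlation_matrix(table: pd.DataFrame,
                       variables=MARKER_VARIABLES) -> pd.DataFrame:
    """Symmetric Pearson matrix over the four marker variables."""
    k = len(variables)
    out = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    for i in range(k):
        for j in range(i + 1, k):
            r = pearson_r(table[variables[i]], table[variables[j]])
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def ols_fit(x, y) -> RegressionFit:
    """Least-squares fit of y on x (e.g. MIB-1 on PhH3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise InvalidParameterError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         pearson_r=float(res.rvalue))


def classify_above_line(table: pd.DataFrame, fit: RegressionFit,
                        x_col: str = "phh3_per_field",
                        y_col: str = "mib1_per_field",
                        ) -> tuple[pd.Series, ContingencyTable2x2]:
    """Flag tumors strictly above the regression line and pool grades 1-2 vs 3.

    A tumor exactly on the line counts as *not* above (strict inequality).
    """
    above = table[y_col] > fit.predict(table[x_col])
    low = table["grade"].isin([1, 2])
    ct = ContingencyTable2x2(
        a=int((above & low).sum()),
        b=int((~above & low).sum()),
        c=int((above & ~low).sum()),
        d=int((~above & ~low).sum()),
    )
    return above.rename("above_line"), ct


def fisher_exact_2x2(t: ContingencyTable2x2, tie_rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    With margins fixed, every table is indexed by its top-left cell; the
    p-value sums the probabilities of all tables whose point probability does
    not exceed the observed one (within a small relative tolerance for
    floating-point ties). A zero margin admits only the observed table: p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + tie_rel_tol)].sum())
    return min(p, 1.0)


def two_sample_t(group_low, group_high, welch: bool = False) -> tuple[float, float]:
    """Independent-samples t-test (pooled variance by default) -> (t, two-sided p).

    Used to compare grades 1-2 pooled against grade 3 for each variable.
    """
    x = np.asarray(group_low, dtype=float)
    y = np.asarray(group_high, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("each group needs n >= 2")
    if not welch and np.ptp(x) == 0 and np.ptp(y) == 0:
        raise InvalidParameterError("zero pooled variance; t undefined")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def grade_summary(table: pd.DataFrame,
                  variables=MARKER_VARIABLES) -> pd.DataFrame:
    """Mean and sample (n-1) sd per grade and overall, for each variable.

    Grades with a single tumor report a missing sd.
    """
    frames = []
    for grade, sub in table.groupby("grade"):
        row = {"grade": str(grade), "n": len(sub)}
        for v in variables:
            row[f"{v}_mean"] = float(sub[v].mean())
            row[f"{v}_sd"] = float(sub[v].std(ddof=1)) if len(sub) > 1 else np.nan
        frames.append(row)
    overall = {"grade": "all", "n": len(table)}
    for v in variables:
        overall[f"{v}_mean"] = float(table[v].mean())
        overall[f"{v}_sd"] = float(table[v].std(ddof=1)) if len(table) > 1 else np.nan
    frames.append(overall)
    return pd.DataFrame(frames).set_index("grade")
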