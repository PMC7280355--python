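"""Inferential procedures for the timing-accuracy analyses.

Thin, validated wrappers around scipy/statsmodels for the tests the
pipelines report: pooled two-proportion z tests with Holm-Bonferroni
correction for percent-exact comparisons, Welch t and Levene tests for RT
overestimation means and variances, and the Pearson correlation underlying
the reliability statistic.  Pairwise drivers run every group pair within
one analysis as a single Holm family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "TestResult",
    "two_proportion_z",
    "holm_bonferroni",
    "welch_t",
    "levene",
    "pearson_r",
    "pairwise_proportion_tests",
    "pairwise_group_tests",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    df: float | None = None
    labels: tuple | None = None


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sided two-proportion z test with pooled variance under the null.

    A pooled proportion of exactly 0 or 1 leaves the statistic undefined;
    the p value is then reported as 1 (the proportions are identical).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n, n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(statistic=float("nan"), pvalue=1.0)
    stat, p = proportions_ztest(np.array([x1, x2]), np.array([n1, n2]))
    return TestResult(statistic=float(stat), pvalue=float(p))


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm step-down correction: (reject decisions, adjusted p values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                      df=float(res.df))


def levene(a, b, center: str = "mean") -> TestResult:
    """Levene's test for equality of variances between two groups.

    ``center='mean'`` is the classic variant; ``'median'`` gives the
    Brown-Forsythe robustification.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    stat, p = sps.levene(a, b, center=center)
    return TestResult(statistic=float(stat), pvalue=float(p),
                      df=float(a.size + b.size - 2))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN when either variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def _holm_frame(rows: list[dict], alpha: float) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    reject, p_adj = holm_bonferroni(df["pvalue"].to_numpy(), alpha=alpha)
    df["p_holm"] = p_adj
    df["reject"] = reject
    return df


def pairwise_proportion_tests(
    table: pd.DataFrame,
    label_col: str = "label",
    successes_col: str = "successes",
    n_col: str = "n",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs two-proportion z tests over a tidy count table, Holm-corrected
    as one family."""
    rows = []
    recs = table[[label_col, successes_col, n_col]].itertuples(index=False)
    for (la, xa, na), (lb, xb, nb) in itertools.combinations(list(recs), 2):
        res = two_proportion_z(int(xa), int(na), int(xb), int(nb))
        rows.append(
            {"group_a": la, "group_b": lb, "statistic": res.statistic,
             "pvalue": res.pvalue}
        )
    return _holm_frame(rows, alpha)


def pairwise_group_tests(
    groups: Mapping[str, Sequence[float]],
    kind: str = "welch",
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """All-pairs Welch t or Levene tests over labeled value groups,
    Holm-corrected as one family."""
    test = {"welch": welch_t, "levene": levene}.get(kind)
    if test is None:
        raise ValueError("kind must be 'welch' or 'levene'")
    rows = []
    for la, lb in itertools.combinations(sorted(groups), 2):
        res = test(groups[la], groups[lb], **kwargs)
        rows.append(
            {"group_a": la, "group_b": lb, "statistic": res.statistic,
             "pvalue": res.pvalue, "df": res.df}
        )
    return _holm_frame(rows, alpha)
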