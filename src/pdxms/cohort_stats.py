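"""Exploratory success-vs-failure group comparisons.

Continuous variables get Welch two-sample t-tests, categorical variables
Pearson chi-square (or Fisher's exact test when expected counts are small),
and :func:`summarize_groups` assembles the whole characteristics table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    """One row of a success-vs-failure characteristics table."""

    variable: str
    test: str
    statistic: float | None
    p_value: float | None
    # continuous: {"group0": (mean, sd, n), "group1": ...}
    # categorical: {"group0": {level: count}, "group1": ...}
    summary: dict = field(default_factory=dict)
    testable: bool = True
    note: str = ""


def ttest_groups(values0, values1, variable: str = "",
                 equal_var: bool = False) -> GroupComparison:
    """Two-sample t-test (Welch by default, pooled via ``equal_var=True``)."""
    x0 = np.asarray(values0, dtype=float)
    x1 = np.asarray(values1, dtype=float)
    x0, x1 = x0[~np.isnan(x0)], x1[~np.isnan(x1)]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs at least 2 values")
    summary = {"group0": (float(x0.mean()), float(x0.std(ddof=1)), len(x0)),
               "group1": (float(x1.mean()), float(x1.std(ddof=1)), len(x1))}
    if x0.std(ddof=1) == 0.0 and x1.std(ddof=1) == 0.0 and x0.mean() == x1.mean():
        # identical constant groups: no evidence of a difference
        return GroupComparison(variable, "welch t" if not equal_var else "pooled t",
                               0.0, 1.0, summary)
    res = stats.ttest_ind(x0, x1, equal_var=equal_var)
    return GroupComparison(variable,
                           "welch t" if not equal_var else "pooled t",
                           float(res.statistic), float(res.pvalue), summary)


def _fisher_rxc(table: np.ndarray) -> float:
    """Exact conditional p for an r x c table by enumeration.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (the standard two-sided convention).  Feasible only for small tables.
    """
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    log_fact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))

    def log_prob(t: np.ndarray) -> float:
        lp = (log_fact[row_sums].sum() + log_fact[col_sums].sum()
              - log_fact[n] - log_fact[t].sum())
        return lp

    obs_lp = log_prob(table)
    r, c = table.shape

    def rows_with_sum(total: int, cols: np.ndarray):
        """All nonnegative integer rows with given total and column caps."""
        if len(cols) == 1:
            if total <= cols[0]:
                yield (total,)
            return
        for v in range(min(total, cols[0]) + 1):
            for rest in rows_with_sum(total - v, cols[1:]):
                yield (v, *rest)

    p = 0.0

    def recurse(i: int, remaining_cols: np.ndarray, rows: list) -> None:
        nonlocal p
        if i == r - 1:
            t = np.array(rows + [tuple(remaining_cols)])
            if (remaining_cols >= 0).all():
                lp = log_prob(t)
                if lp <= obs_lp + 1e-12:
                    p += math.exp(lp)
            return
        for row in rows_with_sum(int(row_sums[i]), remaining_cols):
            recurse(i + 1, remaining_cols - np.array(row), rows + [row])

    recurse(0, col_sums.copy(), [])
    return min(p, 1.0)


def chisq_or_fisher(counts, variable: str = "",
                    method: str = "auto") -> GroupComparison:
    """Association test for an r x c count table.

    With ``method="auto"`` the Pearson statistic (no continuity
    correction) is used when every expected count is at least 5, and
    Fisher's exact test otherwise (scipy's 2x2 exact test, or full
    enumeration for larger tables with total count <= 200; sparse r x c
    tables too large to enumerate fall back to Pearson with an explanatory
    note on the result).  ``"pearson"``,
    ``"yates"`` (continuity-corrected chi-square, the 2x2 default of many
    clinical reports) and ``"fisher"`` force one procedure.
    """
    table = np.asarray(counts)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("counts must be a nonnegative 2-D table")
    if not np.array_equal(table, np.round(table)):
        raise ValueError("counts must be integers")
    table = table.astype(int)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table to test association")
    zero_rows = np.flatnonzero(table.sum(axis=1) == 0)
    zero_cols = np.flatnonzero(table.sum(axis=0) == 0)
    if len(zero_rows) or len(zero_cols):
        raise ValueError(
            f"degenerate margins: zero rows {zero_rows.tolist()}, "
            f"zero columns {zero_cols.tolist()}")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    note = ""
    if method == "auto":
        method = "pearson" if (expected >= 5).all() else "fisher"
        if (method == "fisher" and table.shape != (2, 2)
                and table.sum() > 200):
            # exact enumeration infeasible: report Pearson, flagged
            method = "pearson"
            note = "expected counts < 5 but exact r x c test infeasible"
    if method in ("pearson", "yates"):
        res = stats.chi2_contingency(table, correction=(method == "yates"))
        name = "chi-square (yates)" if method == "yates" else "chi-square"
        return GroupComparison(variable, name, float(res.statistic),
                               float(res.pvalue), note=note)
    if method != "fisher":
        raise ValueError(f"unknown method {method!r}")
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        return GroupComparison(variable, "fisher exact", None, float(p))
    if table.sum() > 200:
        raise ValueError("exact r x c test infeasible for tables this large")
    return GroupComparison(variable, "fisher exact (enumeration)", None,
                           _fisher_rxc(table))


def summarize_groups(cohort: pd.DataFrame, outcome: str,
                     variables: list[str] | None = None,
                     equal_var: bool = False) -> list[GroupComparison]:
    """Success-vs-failure characteristics table for a cohort.

    Numeric columns are compared with t-tests (group mean +/- SD reported),
    everything else with chi-square/Fisher on the level-by-outcome counts.
    Variables that cannot be tested (constant within both groups, or a
    single observed level) are returned flagged ``testable=False`` rather
    than raising.
    """
    y = cohort[outcome]
    levels = sorted(pd.unique(y.dropna()))
    if len(levels) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary, saw {levels}")
    g0 = cohort[y == levels[0]]
    g1 = cohort[y == levels[1]]
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (outcome, "case_id")]
    out: list[GroupComparison] = []
    for var in variables:
        if pd.api.types.is_numeric_dtype(cohort[var]):
            try:
                out.append(ttest_groups(g0[var], g1[var], variable=var,
                                        equal_var=equal_var))
            except ValueError as exc:
                out.append(GroupComparison(var, "welch t", None, None,
                                           testable=False, note=str(exc)))
            continue
        tab = pd.crosstab(cohort[var], y)
        summary = {"group0": tab[levels[0]].to_dict() if levels[0] in tab else {},
                   "group1": tab[levels[1]].to_dict() if levels[1] in tab else {}}
        try:
            cmp_ = chisq_or_fisher(tab.to_numpy(), variable=var)
            cmp_.summary = summary
            out.append(cmp_)
        except ValueError as exc:
            out.append(GroupComparison(var, "chi-square", None, None,
                                       summary=summary, testable=False,
                                       note=str(exc)))
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons to a tidy frame (one row per variable)."""
    rows = []
    for c in comparisons:
        rows.append({"variable": c.variable, "test": c.test,
                     "statistic": c.statistic, "p_value": c.p_value,
                     "testable": c.testable, "note": c.note,
                     "summary": repr(c.summary)})
    return pd.DataFrame(rows)


def category_share(counts: dict[str, tuple[int, int]], category: str,
                   group: int = 1) -> float:
    """Share of one category within an outcome group, in percent.

    E.g. the success-group share of a tumour subtype from printed
    outcome-by-category counts.
    """
    idx = 1 if group == 1 else 0
    total = sum(v[idx] for v in counts.values())
    if total == 0:
        raise ValueError("empty outcome group")
    return 100.0 * counts[category][idx] / total


def engraftment_rate(n_success: int, n_total: int) -> float:
    """Engraftment success rate in percent."""
    if n_total <= 0 or not 0 <= n_success <= n_total:
        raise ValueError("need 0 <= n_success <= n_total with n_total > 0")
    return 100.0 * n_success / n_total
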