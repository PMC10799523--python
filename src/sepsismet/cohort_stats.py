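"""Survivor vs non-survivor characterisation: exact and rank tests per feature.

Discrete variables are compared with Fisher's exact test (two-sided by the
minimum-likelihood rule: sum the probabilities of all tables with the same
margins that are no more probable than the observed one); continuous
variables with the Mann-Whitney U test. Summaries use counts for discrete
features and median (lower/upper quartile) for continuous ones, quartiles by
type-7 linear interpolation so printed tables are deterministic.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FisherResult", "ComparisonRow", "fisher_exact", "mann_whitney", "compare_groups"]

_REL_TOL = 1e-9  # tables within this relative probability of the observed count


@dataclass
class FisherResult:
    p_value: float
    method: str  # exact | enumeration | monte_carlo
    mc_se: float | None = None


@dataclass
class ComparisonRow:
    feature: str
    test_used: str  # fisher | mann_whitney
    group_a: str
    group_b: str
    summary_a: str
    summary_b: str
    p_value: float
    degenerate: bool = False


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("contingency table must contain integers")
        table = np.round(table).astype(np.int64)
    if np.any(table < 0):
        raise ValueError("contingency table counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    return table.astype(np.int64)


def _log_table_prob(table: np.ndarray, row_m: np.ndarray, col_m: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins."""
    n = int(row_m.sum())
    val = (
        sum(math.lgamma(r + 1) for r in row_m)
        + sum(math.lgamma(c + 1) for c in col_m)
        - math.lgamma(n + 1)
        - sum(math.lgamma(int(x) + 1) for x in table.ravel())
    )
    return val


def _enumerate_tables(row_m, col_m):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_m), len(col_m)

    def rec(i, cols_left, rows):
        if i == r - 1:
            last = cols_left
            if np.all(last >= 0) and last.sum() == row_m[-1]:
                yield rows + [last]
            return
        # enumerate row i summing to row_m[i] with cell j <= cols_left[j]
        def row_fill(j, remaining, cur):
            if j == c - 1:
                if 0 <= remaining <= cols_left[j]:
                    yield cur + [remaining]
                return
            for x in range(min(remaining, cols_left[j]) + 1):
                yield from row_fill(j + 1, remaining - x, cur + [x])

        for row in row_fill(0, int(row_m[i]), []):
            row = np.array(row)
            yield from rec(i + 1, cols_left - row, rows + [row])

    yield from rec(0, col_m.copy(), [])


def fisher_exact(
    table,
    seed: int = 0,
    mc_samples: int = 100_000,
    enumeration_limit: int = 200,
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c table (minimum-likelihood rule).

    2x2 tables use the standard hypergeometric computation; larger tables
    with total count <= ``enumeration_limit`` are handled by full
    enumeration over all tables with the observed margins; beyond that a
    seeded Monte-Carlo estimate (Patefield sampling) is returned with its
    standard error.
    """
    table = _validate_table(table)
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return FisherResult(p_value=float(p), method="exact")
    row_m, col_m = table.sum(axis=1), table.sum(axis=0)
    lp_obs = _log_table_prob(table, row_m, col_m)
    if table.sum() <= enumeration_limit:
        total = 0.0
        for t in _enumerate_tables(row_m, col_m):
            lp = _log_table_prob(np.array(t), row_m, col_m)
            if lp <= lp_obs + _REL_TOL:
                total += math.exp(lp)
        return FisherResult(p_value=min(total, 1.0), method="enumeration")
    dist = stats.random_table(row_m, col_m, seed=np.random.default_rng(seed))
    draws = dist.rvs(mc_samples)
    lps = np.array([_log_table_prob(t, row_m, col_m) for t in draws])
    hits = lps <= lp_obs + _REL_TOL
    p = float(hits.mean())
    se = float(np.sqrt(p * (1 - p) / mc_samples))
    return FisherResult(p_value=p, method="monte_carlo", mc_se=se)


def mann_whitney(a, b) -> tuple[float, float, bool]:
    """Mann-Whitney U (midranks for ties) with two-sided p.

    Exact enumeration when the pooled size is <= 20 with no ties, normal
    approximation with tie and continuity correction otherwise. Returns
    (U for sample ``a``, p, degenerate-flag); pooled samples that are all
    identical are degenerate: U = n_a*n_b/2, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0, True
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), False


def _quartile_summary(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 linear interpolation
    return f"{med:g} ({q1:g}-{q3:g})"


def _count_summary(x: pd.Series) -> str:
    counts = x.value_counts().sort_index()
    return ", ".join(f"{k}-{v}" for k, v in counts.items())


def compare_groups(
    clinical: pd.DataFrame,
    grouping_column: str,
    discrete: list[str] | None = None,
    continuous: list[str] | None = None,
    include_missing_category: bool = False,
) -> list[ComparisonRow]:
    """Per-feature two-group comparison table (Fisher or Mann-Whitney).

    Features not listed explicitly are classified automatically: numeric
    columns with more than two distinct observed values are continuous,
    everything else discrete. Missing values are dropped unless
    ``include_missing_category`` is set, in which case they form their own
    category for discrete features.
    """
    if grouping_column not in clinical.columns:
        raise ValueError(f"unknown grouping column {grouping_column!r}")
    g = clinical[grouping_column]
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise ValueError("grouping column must have exactly two levels present")
    ga, gb = (g == levels[0]), (g == levels[1])
    discrete = set(discrete or [])
    continuous = set(continuous or [])
    rows: list[ComparisonRow] = []
    for col in clinical.columns:
        if col == grouping_column:
            continue
        s = clinical[col]
        if col in continuous or (
            col not in discrete
            and pd.api.types.is_numeric_dtype(s)
            and s.dropna().nunique() > 2
        ):
            xa, xb = s[ga].dropna().to_numpy(), s[gb].dropna().to_numpy()
            if xa.size == 0 or xb.size == 0:
                raise ValueError(f"feature {col!r} empty in one group")
            _, p, degen = mann_whitney(xa, xb)
            rows.append(
                ComparisonRow(
                    feature=col,
                    test_used="mann_whitney",
                    group_a=str(levels[0]),
                    group_b=str(levels[1]),
                    summary_a=_quartile_summary(xa),
                    summary_b=_quartile_summary(xb),
                    p_value=p,
                    degenerate=degen,
                )
            )
        else:
            sa, sb = s[ga], s[gb]
            if include_missing_category:
                sa = sa.astype(object).where(sa.notna(), "missing")
                sb = sb.astype(object).where(sb.notna(), "missing")
            else:
                sa, sb = sa.dropna(), sb.dropna()
            cats = sorted(set(sa.unique()) | set(sb.unique()), key=str)
            tab = np.array(
                [
                    [int((sa == c).sum()) for c in cats],
                    [int((sb == c).sum()) for c in cats],
                ]
            )
            tab = tab[:, tab.sum(axis=0) > 0]
            res = fisher_exact(tab)
            rows.append(
                ComparisonRow(
                    feature=col,
                    test_used="fisher",
                    group_a=str(levels[0]),
                    group_b=str(levels[1]),
                    summary_a=_count_summary(sa),
                    summary_b=_count_summary(sb),
                    p_value=res.p_value,
                )
            )
    return rows


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Long-format DataFrame of a comparison, ready for CSV/JSON export."""
    return pd.DataFrame([r.__dict__ for r in rows])
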