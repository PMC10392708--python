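"""Clinicopathologic group statistics.

Exact RxC Fisher tests by full enumeration of the fixed-margins fiber
(the probability-mass two-sided rule used by mainstream exact-test
implementations), Wilcoxon rank-sum with tie correction and continuity
correction, Kruskal-Wallis, Dunn post-hoc pairwise comparisons with
Bonferroni adjustment, and median/IQR summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import gammaln

#: relative tolerance of the probability-mass two-sided Fisher rule
_FISHER_RELTOL = 1e-7


@dataclass
class GroupTestResult:
    statistic: float
    p: float
    method: str
    pairwise: list[tuple[tuple, float, float]] | None = None  # (pair, z, p_adj)


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n, base: float) -> float:
    """log multivariate hypergeometric probability of a fixed-margins table."""
    return base - gammaln(table + 1.0).sum()


def _enumerate_fiber(row_sums: np.ndarray, col_sums: np.ndarray):
    """Yield every nonnegative integer table with the given margins."""
    R, C = len(row_sums), len(col_sums)
    table = np.zeros((R, C), dtype=np.int64)

    def fill_row(r: int, remaining_cols: np.ndarray):
        if r == R - 1:
            if np.all(remaining_cols >= 0):
                table[r] = remaining_cols
                if remaining_cols.sum() == row_sums[r]:
                    yield table
            return
        yield from fill_cell(r, 0, row_sums[r], remaining_cols)

    def fill_cell(r: int, c: int, row_left: int, remaining_cols: np.ndarray):
        if c == C - 1:
            if 0 <= row_left <= remaining_cols[c]:
                table[r, c] = row_left
                rc = remaining_cols.copy()
                rc[c] -= row_left
                yield from fill_row(r + 1, rc)
            return
        hi = min(row_left, remaining_cols[c])
        for v in range(hi + 1):
            table[r, c] = v
            rc = remaining_cols.copy()
            rc[c] -= v
            yield from fill_cell(r, c + 1, row_left - v, rc)

    yield from fill_row(0, col_sums.copy())


def fisher_exact(table, budget: int = 10_000, mc: int | None = None,
                 seed: int | None = None) -> GroupTestResult:
    """Exact two-sided Fisher test for an RxC contingency table.

    The p-value is the total null probability (fixed-margins
    multivariate hypergeometric) of all tables at most as probable as
    the observed one (relative tolerance 1 + 1e-7); 2x2 tables follow
    the same rule. Tables whose total exceeds ``budget`` raise, with a
    Monte-Carlo fallback available through ``mc`` (number of sampled
    tables from the null).
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    n = int(obs.sum())
    if n == 0:
        raise ValueError("table total must be positive")
    row_sums, col_sums = obs.sum(axis=1), obs.sum(axis=0)
    base = (gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum()
            - gammaln(n + 1.0))
    logp_obs = _log_table_prob(obs, row_sums, col_sums, n, base)
    cutoff = logp_obs + np.log1p(_FISHER_RELTOL)

    if n > budget:
        if mc is None:
            raise ValueError(
                f"table total {n} exceeds the enumeration budget {budget}; "
                "pass mc=N for a Monte-Carlo estimate")
        rng = np.random.default_rng(seed)
        row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
        col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(mc):
            perm = rng.permutation(col_labels)
            t = np.zeros_like(obs)
            np.add.at(t, (row_labels, perm), 1)
            if _log_table_prob(t, row_sums, col_sums, n, base) <= cutoff:
                hits += 1
        return GroupTestResult(statistic=float(np.exp(logp_obs)),
                               p=max(hits, 1) / mc, method="fisher")

    p = 0.0
    for t in _enumerate_fiber(row_sums, col_sums):
        logp = _log_table_prob(t, row_sums, col_sums, n, base)
        if logp <= cutoff:
            p += float(np.exp(logp))
    return GroupTestResult(statistic=float(np.exp(logp_obs)),
                           p=min(p, 1.0), method="fisher")


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> GroupTestResult:
    """Two-sided rank-sum test, normal approximation with tie correction.

    Midranks handle ties; the variance is tie-corrected and a 0.5
    continuity correction is applied by default. Fully tied data gives
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied across both samples; p = 1")
        return GroupTestResult(statistic=float(x.size * y.size / 2), p=1.0,
                               method="wilcoxon")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=continuity)
    return GroupTestResult(statistic=float(res.statistic),
                           p=float(min(res.pvalue, 1.0)), method="wilcoxon")


def kruskal_wallis(groups: list) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(statistic=0.0, p=1.0, method="kruskal_wallis")
    h, p = stats.kruskal(*groups)
    return GroupTestResult(statistic=float(h), p=float(p), method="kruskal_wallis")


def dunn_posthoc(groups: list, labels: list | None = None) -> GroupTestResult:
    """Dunn's pairwise mean-rank comparisons after Kruskal-Wallis.

    z for a pair (i, j) is the mean-rank difference over the pooled
    midranks divided by sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided p-values are
    Bonferroni-adjusted over all k(k-1)/2 pairs (Dunn's original
    proposal).
    """
    omnibus = kruskal_wallis(groups)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = pooled.size
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i, j in combinations(range(len(groups)), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
        pairwise.append(((labels[i], labels[j]), float(z), float(p_adj)))
    return GroupTestResult(statistic=omnibus.statistic, p=omnibus.p,
                           method="dunn", pairwise=pairwise)


def summarize_median_iqr(x) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation of order statistics."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)
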