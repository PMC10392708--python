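"""Two-group differential expression with Benjamini-Yekutieli FDR.

Per-gene Welch (unequal-variance) t-tests on log2 normalized data, a
fold change defined as the difference of group means on the log2 scale,
Benjamini-Yekutieli adjustment across the endogenous genes of the
merged panel, and volcano-style up/down/ns classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

FLAG_UP = "up"
FLAG_DOWN = "down"
FLAG_NS = "ns"


def de_test(merged_log2: ExpressionMatrix, groups: pd.Series,
            ref_level: str | None = None) -> pd.DataFrame:
    """Per-gene Welch t-test between the two levels of ``groups``.

    ``log2fc`` is mean(log2, test group) - mean(log2, reference group);
    the reference defaults to the lexicographically smaller level. Only
    endogenous genes are tested. Genes with zero variance in both
    groups and equal means get p = 1.

    Returns a DataFrame with columns gene, log2fc, p_raw (p_by unset).
    """
    if merged_log2.scale != "log2":
        raise ValueError("de_test expects a log2-scale matrix")
    groups = pd.Series(groups)
    if groups.index.dtype == np.int64 and len(groups) == len(merged_log2.sample_names):
        groups.index = merged_log2.sample_names
    groups = groups.reindex(merged_log2.sample_names)
    if groups.isna().any():
        raise ValueError("group labels must cover every sample")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if ref_level is None:
        ref_level = levels[0]
    if ref_level not in levels:
        raise ValueError(f"reference level {ref_level!r} not among {levels}")
    test_level = [lv for lv in levels if lv != ref_level][0]

    genes = merged_log2.endogenous_genes
    a = merged_log2.values.loc[genes, groups[groups == test_level].index].to_numpy()
    b = merged_log2.values.loc[genes, groups[groups == ref_level].index].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate genes: zero variance in both groups
    degenerate = np.isnan(p)
    p = np.where(degenerate & np.isclose(log2fc, 0.0), 1.0, p)
    p = np.where(np.isnan(p), np.nextafter(0, 1), p)  # zero variance, unequal means
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({"gene": genes, "log2fc": log2fc, "p_raw": p})


def adjust_by(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values, returned in input order.

    The BY procedure inflates Benjamini-Hochberg by the harmonic number
    c(m) = sum_{i<=m} 1/i, remaining valid under arbitrary dependence
    between tests.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_by")[1]


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (used by the ORA stage)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def classify_volcano(results: pd.DataFrame, p_thresh: float = 0.05,
                     lfc_thresh: float = 1.0) -> pd.DataFrame:
    """Label genes up/down/ns by unadjusted p and log2 fold change.

    up: p_raw < p_thresh and log2fc > lfc_thresh; down: p_raw < p_thresh
    and log2fc < -lfc_thresh; everything else ns.
    """
    if p_thresh <= 0 or lfc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    sig = out["p_raw"] < p_thresh
    out["flag"] = np.select(
        [sig & (out["log2fc"] > lfc_thresh), sig & (out["log2fc"] < -lfc_thresh)],
        [FLAG_UP, FLAG_DOWN], default=FLAG_NS)
    return out


def differential_expression(merged_log2: ExpressionMatrix, groups: pd.Series,
                            ref_level: str | None = None, p_thresh: float = 0.05,
                            lfc_thresh: float = 1.0) -> pd.DataFrame:
    """Full DE stage: Welch tests, BY adjustment, volcano flags."""
    res = de_test(merged_log2, groups, ref_level=ref_level)
    res["p_by"] = adjust_by(res["p_raw"].to_numpy())
    return classify_volcano(res, p_thresh=p_thresh, lfc_thresh=lfc_thresh)
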