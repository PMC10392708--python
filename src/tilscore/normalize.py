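"""Reference-gene selection, housekeeping normalization, and panel merge.

The normalization strategy for two overlapping targeted panels:

1. rank candidate reference (housekeeping) genes by geNorm expression
   stability M — the mean, over all other candidates, of the standard
   deviation across samples of the pairwise log2 ratio — with the
   pairwise-variation statistic V(n, n+1) deciding how many to keep;
2. scale each sample by the ratio of the cohort-average reference
   geometric mean to that sample's reference geometric mean, per panel
   independently;
3. merge the panels by the ratio of geometric means of all common
   probes: the second panel is rescaled by that ratio, common probes
   are averaged entrywise, and unique probes are carried through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import PSEUDOCOUNT, ExpressionMatrix, geomean_with_floor

log = logging.getLogger(__name__)


@dataclass
class GeNormResult:
    m_values: pd.Series          # stability M per candidate (elimination-round M)
    ranking: list[str]           # most -> least stable
    pairwise_variation: pd.Series  # V(n, n+1) indexed by n
    selected: list[str]          # final reference gene list

    def __post_init__(self) -> None:
        if (self.m_values < 0).any():
            raise ValueError("stability M must be nonnegative")
        if len(self.selected) < 2:
            raise ValueError("at least two reference genes must be selected")
        if sorted(self.ranking) != sorted(self.m_values.index):
            raise ValueError("ranking must permute the candidate set")


def _stability_m(log2_expr: pd.DataFrame) -> pd.Series:
    """geNorm M for every candidate against the current candidate set."""
    arr = log2_expr.to_numpy(dtype=float)
    genes = list(log2_expr.index)
    m = np.zeros(len(genes))
    for j in range(len(genes)):
        sds = [np.std(arr[j] - arr[k], ddof=1)
               for k in range(len(genes)) if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=genes)


def genorm_stability(log2_expr: pd.DataFrame, min_refs: int = 3,
                     v_threshold: float = 0.15) -> GeNormResult:
    """Rank candidate reference genes by geNorm expression stability.

    Parameters
    ----------
    log2_expr
        Candidate-gene x sample matrix of log2 expression.
    min_refs
        Smallest reference set considered; the conventional default is 3.
    v_threshold
        Pairwise-variation cutoff: the selected set is the smallest
        ``n >= min_refs`` with ``V(n, n+1) < v_threshold`` (all
        candidates if no n qualifies). 0.15 is the conventional cutoff.

    The reported per-candidate M is computed against the full candidate
    set; the ranking comes from iterative exclusion of the least stable
    gene, recomputing M among the survivors each round (ties eliminate
    the later-listed candidate, so a fully degenerate matrix ranks by
    input order; the final two genes share a pairwise SD and keep their
    input order).
    """
    if log2_expr.shape[0] < 3:
        raise ValueError("geNorm requires at least 3 candidate genes")
    if log2_expr.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    if not np.all(np.isfinite(log2_expr.to_numpy(dtype=float))):
        raise ValueError("log2 expression must be finite")

    m_values = _stability_m(log2_expr)
    remaining = log2_expr.copy()
    elimination: list[str] = []
    while remaining.shape[0] > 2:
        m = _stability_m(remaining)
        # argmax with ties broken toward the later-listed candidate
        worst = m[m >= m.max() - 1e-300].index[-1]
        elimination.append(worst)
        remaining = remaining.drop(index=worst)
    ranking = list(remaining.index) + elimination[::-1]

    # V(n, n+1): SD across samples of the change in the log2 normalization
    # factor (mean log2 of the top-n genes) when adding gene n+1
    arr = log2_expr.loc[ranking].to_numpy(dtype=float)
    v = {}
    for n in range(2, len(ranking)):
        nf_n = arr[:n].mean(axis=0)
        nf_n1 = arr[:n + 1].mean(axis=0)
        v[n] = float(np.std(nf_n1 - nf_n, ddof=1))
    pairwise_variation = pd.Series(v, dtype=float)

    selected = list(ranking)
    for n in sorted(v):
        if n >= min_refs and v[n] < v_threshold:
            selected = ranking[:n]
            break
    return GeNormResult(m_values=m_values, ranking=ranking,
                        pairwise_variation=pairwise_variation, selected=selected)


@dataclass
class NormalizationResult:
    matrix: ExpressionMatrix
    size_factors: pd.Series       # applied per-sample factor f_s
    excluded_samples: list[str]   # samples failing reference-count QC
    refs: list[str]


def housekeeping_normalize(raw: ExpressionMatrix, refs: list[str],
                           qc_min: float = 20.0) -> NormalizationResult:
    """Scale each sample by its reference-gene geometric mean.

    ``f_s = (cohort mean of per-sample reference geomeans) / (reference
    geomean of sample s)``, with geomeans taken on counts + 0.5. Samples
    whose reference geomean falls below ``qc_min`` are flagged and
    excluded before the cohort mean is taken — the too-few-read-counts
    QC rule.
    """
    missing = set(refs) - set(raw.gene_names)
    if missing:
        raise KeyError(f"reference genes absent from matrix: {sorted(missing)}")
    if raw.scale != "raw_counts":
        raise ValueError("housekeeping_normalize expects raw counts")

    ref_vals = raw.values.loc[list(refs)].to_numpy(dtype=float) + PSEUDOCOUNT
    geomeans = pd.Series(np.exp(np.mean(np.log(ref_vals), axis=0)),
                         index=raw.sample_names)
    keep = geomeans >= qc_min
    excluded = list(geomeans.index[~keep])
    if excluded:
        log.warning("panel %s: excluding %d sample(s) failing reference QC "
                    "(geomean < %g): %s", raw.panel_id, len(excluded), qc_min,
                    ", ".join(excluded))
    if keep.sum() == 0:
        raise ValueError("all samples failed reference-count QC")
    kept_geomeans = geomeans[keep]
    factors = kept_geomeans.mean() / kept_geomeans
    factors.name = "size_factor"
    normalized = raw.values.loc[:, list(kept_geomeans.index)].mul(factors, axis=1)
    matrix = replace(raw, values=normalized, probe_class=raw.probe_class.copy(),
                     scale="normalized")
    return NormalizationResult(matrix=matrix, size_factors=factors,
                               excluded_samples=excluded, refs=list(refs))


def merge_panels(first: ExpressionMatrix, second: ExpressionMatrix) -> ExpressionMatrix:
    """Merge two normalized panels via the common-probe geomean ratio.

    The ratio of geometric means of all common probes (first over
    second, pooled over all samples) rescales every probe of the second
    panel; common probes are then averaged entrywise and unique probes
    carried through unchanged (second panel's rescaled).
    """
    for em in (first, second):
        if em.scale != "normalized":
            raise ValueError("merge_panels expects normalized matrices")
    if set(first.sample_names) != set(second.sample_names):
        raise ValueError("panels must share an identical sample set")
    common = [g for g in first.gene_names if g in set(second.gene_names)]
    if not common:
        raise ValueError("no common probes between panels")
    second_vals = second.values[first.sample_names]

    r = (geomean_with_floor(first.values.loc[common].to_numpy())
         / geomean_with_floor(second_vals.loc[common].to_numpy()))
    log.info("merge: %d common probes, scaling ratio %.6g (%s over %s)",
             len(common), r, first.panel_id, second.panel_id)
    scaled_second = second_vals * r

    merged_common = (first.values.loc[common] + scaled_second.loc[common]) / 2.0
    unique_first = [g for g in first.gene_names if g not in set(common)]
    unique_second = [g for g in second.gene_names if g not in set(common)]
    values = pd.concat([merged_common, first.values.loc[unique_first],
                        scaled_second.loc[unique_second]])
    probe_class = pd.concat([first.probe_class.loc[common + unique_first],
                             second.probe_class.loc[unique_second]])
    return ExpressionMatrix(values=values, probe_class=probe_class,
                            panel_id=f"{first.panel_id}+{second.panel_id}",
                            scale="normalized")
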