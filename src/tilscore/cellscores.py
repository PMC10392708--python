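"""Marker-gene immune cell scores and TIL-relative normalization.

A cell type's raw score is the arithmetic mean of its marker genes'
log2 expression in a sample. The TIL composite averages the raw scores
of B cells, T cells, CD45, macrophages, and cytotoxic cells. A relative
score divides a cell type's (geometric-mean) expression by a
denominator's — on the log2 scale that ratio is a difference of raw
scores, which is how it is computed here. Centered scores subtract the
cohort mean per (cell type, denominator) row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .matrix import ExpressionMatrix
from .synth import TIL_COMPONENTS, MarkerMap

log = logging.getLogger(__name__)

TIL = "TIL"


def raw_cell_scores(merged_log2: ExpressionMatrix, marker_map: MarkerMap) -> pd.DataFrame:
    """Cell type x sample raw scores: mean log2 expression of markers.

    Markers absent from the merged matrix are dropped with a warning; a
    cell type losing every marker is an error naming the type.
    """
    if merged_log2.scale != "log2":
        raise ValueError("raw_cell_scores expects a log2-scale matrix")
    present = set(merged_log2.gene_names)
    rows = {}
    for cell_type, markers in marker_map.entries.items():
        found = [g for g in markers if g in present]
        missing = [g for g in markers if g not in present]
        if missing:
            log.warning("cell type %s: dropping %d absent marker(s): %s",
                        cell_type, len(missing), ", ".join(missing))
        if not found:
            raise ValueError(f"cell type {cell_type!r} has no markers in the matrix")
        rows[cell_type] = merged_log2.values.loc[found].mean(axis=0)
    return pd.DataFrame(rows).T


def til_score(raw: pd.DataFrame) -> pd.Series:
    """Per-sample TIL composite: mean raw score of the five constituents."""
    missing = [c for c in TIL_COMPONENTS if c not in raw.index]
    if missing:
        raise ValueError(f"raw score table missing TIL constituents: {missing}")
    til = raw.loc[list(TIL_COMPONENTS)].mean(axis=0)
    til.name = TIL
    return til


def relative_scores(raw: pd.DataFrame, til: pd.Series,
                    pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Log2-space ratios raw(numerator) - score(denominator).

    The denominator is either ``"TIL"`` or another cell type. Rows are
    indexed by (numerator, denominator) tuples.
    """
    rows = {}
    for num, den in pairs:
        if num not in raw.index:
            raise KeyError(f"unknown cell type {num!r}")
        if den == TIL:
            den_score = til
        elif den in raw.index:
            den_score = raw.loc[den]
        else:
            raise KeyError(f"unknown denominator {den!r}")
        rows[(num, den)] = raw.loc[num] - den_score
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["cell_type", "denominator"])
    return out


def center_scores(relative: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's cohort mean (>= 2 samples required)."""
    if relative.shape[1] < 2:
        raise ValueError("centering needs at least 2 samples")
    return relative.sub(relative.mean(axis=1), axis=0)


@dataclass
class CellScoreTable:
    """Raw, TIL, relative, and centered scores of one cohort."""

    raw: pd.DataFrame
    til: pd.Series
    relative: pd.DataFrame
    centered: pd.DataFrame


def default_pairs(marker_map: MarkerMap) -> list[tuple[str, str]]:
    """Every cell type vs TIL, plus the CD8 exhaustion ratio if present."""
    pairs = [(c, TIL) for c in marker_map.cell_types]
    if "CD8" in marker_map.entries and "exhausted_CD8" in marker_map.entries:
        pairs.append(("CD8", "exhausted_CD8"))
    return pairs


def score_table(merged_log2: ExpressionMatrix, marker_map: MarkerMap,
                pairs: list[tuple[str, str]] | None = None) -> CellScoreTable:
    """Compute the full score stack for a merged log2 matrix."""
    raw = raw_cell_scores(merged_log2, marker_map)
    til = til_score(raw)
    if pairs is None:
        pairs = default_pairs(marker_map)
    rel = relative_scores(raw, til, pairs)
    return CellScoreTable(raw=raw, til=til, relative=rel,
                          centered=center_scores(rel))
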