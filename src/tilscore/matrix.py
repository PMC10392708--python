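"""Gene-by-sample expression container for targeted-panel count data.

An :class:`ExpressionMatrix` carries the values together with per-probe
class labels (endogenous vs housekeeping), the panel identity, and the
scale the values live on (``raw_counts``, ``normalized``, or ``log2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ENDOGENOUS = "endogenous"
HOUSEKEEPING = "housekeeping"
SCALES = ("raw_counts", "normalized", "log2")

#: pseudocount used before any log or geometric mean on counts
PSEUDOCOUNT = 0.5


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with probe metadata.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns.
    probe_class
        Per-gene label, ``endogenous`` or ``housekeeping``, indexed like
        ``values``.
    panel_id
        Name of the codeset/panel the values came from.
    scale
        One of ``raw_counts``, ``normalized``, ``log2``.
    """

    values: pd.DataFrame
    probe_class: pd.Series
    panel_id: str = "panel"
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene names")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        self.probe_class = self.probe_class.reindex(self.values.index)
        if self.probe_class.isna().any():
            raise ValueError("probe_class missing for some genes")
        bad = set(self.probe_class.unique()) - {ENDOGENOUS, HOUSEKEEPING}
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        if self.scale == "raw_counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be nonnegative integers")

    # -- convenience -------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def endogenous_genes(self) -> list[str]:
        return list(self.values.index[self.probe_class == ENDOGENOUS])

    @property
    def housekeeping_genes(self) -> list[str]:
        return list(self.values.index[self.probe_class == HOUSEKEEPING])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(samples)].copy(),
                       probe_class=self.probe_class.copy())

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2 copy; a 0.5 pseudocount keeps zeros finite."""
        if self.scale == "log2":
            return replace(self, values=self.values.copy(),
                           probe_class=self.probe_class.copy())
        vals = np.log2(self.values + PSEUDOCOUNT)
        return replace(self, values=vals, probe_class=self.probe_class.copy(),
                       scale="log2")


def geomean_with_floor(values: np.ndarray, floor: float = PSEUDOCOUNT) -> float:
    """Geometric mean with zero entries floored at ``floor``.

    Zero counts occur in targeted panels; flooring keeps the geometric
    mean finite without shifting strictly positive values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if (v < 0).any():
        raise ValueError("geometric mean requires nonnegative values")
    v = np.where(v < floor, floor, v)
    return float(np.exp(np.mean(np.log(v))))
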