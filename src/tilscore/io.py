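"""Plain-text readers/writers for the pipeline's file dialects.

Count matrices travel as CSV with a ``#`` header line carrying the panel
tag and scale, a ``gene`` key column, a ``probe_class`` column, and one
column per sample. Marker maps are two-column TSV (cell_type, gene).
Clinical tables are ordinary CSV keyed by ``sample``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix


def write_matrix(em: ExpressionMatrix, path) -> None:
    path = Path(path)
    df = em.values.copy()
    df.insert(0, "probe_class", em.probe_class)
    with open(path, "w") as fh:
        fh.write(f"# panel={em.panel_id} scale={em.scale}\n")
        df.to_csv(fh, index_label="gene")


def read_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#' panel header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        body = fh.read()
    df = pd.read_csv(_io.StringIO(body), index_col="gene")
    df.index.name = None
    df.columns.name = None
    probe_class = df.pop("probe_class")
    return ExpressionMatrix(values=df, probe_class=probe_class,
                            panel_id=meta.get("panel", "panel"),
                            scale=meta.get("scale", "raw_counts"))


def write_marker_map(entries: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_type\tgene\n")
        for cell_type, genes in entries.items():
            for g in genes:
                fh.write(f"{cell_type}\t{g}\n")


def read_marker_map_tsv(path) -> dict[str, list[str]]:
    entries: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("cell_type")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            entries.setdefault(parts[0], []).append(parts[1])
    return entries


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path)
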