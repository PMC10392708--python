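"""Overrepresentation analysis of gene lists against GMT collections.

One-sided hypergeometric tail tests of a query gene list's overlap with
each curated set, restricted to a declared universe (by default the
endogenous genes of the merged panel — the only defensible null for a
targeted assay), with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import adjust_bh


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not all(isinstance(g, str) and g for g in genes):
                raise ValueError(f"set {name!r} contains empty gene names")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then >= 1 tab-separated gene.

    Duplicate genes within a set are stored once (first occurrence).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in parts[2:] if g))
    if not sets:
        warnings.warn(f"{path}: empty GMT file; no gene sets loaded")
    return GeneSetCollection(sets=sets)


def ora_test(query: list[str], collection: GeneSetCollection,
             universe: list[str] | None = None) -> pd.DataFrame:
    """Hypergeometric overrepresentation test per gene set.

    For a universe of N genes, a set of size K (after restriction to
    the universe), and a query of size n, the p-value is
    P(X >= k) for X ~ Hypergeometric(N, K, n) where k is the observed
    overlap. Results carry BH-adjusted p-values and are sorted by p.
    """
    universe = universe if universe is not None else collection.universe
    if universe is None:
        raise ValueError("a gene universe is required")
    uni = set(universe)
    q = set(query) & uni
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, genes in collection.sets.items():
        s = set(genes) & uni
        K = len(s)
        overlap = sorted(q & s)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "K": K, "n": n, "k": k,
                     "gene_ratio": k / n, "p": min(p, 1.0),
                     "overlap": ",".join(overlap)})
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)[
        ["set", "K", "n", "k", "gene_ratio", "p", "p_adj", "overlap"]]
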