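"""Over-representation analysis against user-supplied gene sets.

A deliberately simple ORA: for each named gene set, an upper-tail
hypergeometric test of the overlap between a query gene list and the set,
both intersected with a stated background, with BH-FDR across sets. This is
a local stand-in for hosted meta-analysis services — no term clustering or
multi-database merging. Gene sets are read from GMT files
(tab-separated: name, description, member genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._stats import bh_fdr
from .errors import DataError


def _norm_symbol(g: str) -> str:
    return str(g).strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT contents)."""

    sets: dict  # name -> frozenset of gene symbols
    descriptions: dict

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set '{name}' is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict = {}
        descriptions: dict = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise DataError(f"{path}:{lineno}: GMT line needs "
                                    "name, description and >=1 member")
                name, desc, *members = parts
                if name in sets:
                    raise DataError(f"duplicate gene-set name '{name}'")
                members = frozenset(_norm_symbol(m) for m in members if m.strip())
                if not members:
                    raise DataError(f"gene set '{name}' has no members")
                sets[name] = members
                descriptions[name] = desc
        if not sets:
            raise DataError(f"no gene sets in {path}")
        return cls(sets=sets, descriptions=descriptions)

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.descriptions.get(name, "")]
                                   + sorted(members)) + "\n")


def hypergeometric_ora(query, background, sets: GeneSetCollection,
                       q_thresh: float = 0.01) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    ``query`` must be a subset of ``background``; each gene set is
    intersected with the background before testing. Returns a table sorted
    by (q, p) with a ``significant`` flag at ``q < q_thresh``.
    """
    query = frozenset(_norm_symbol(g) for g in query)
    background = frozenset(_norm_symbol(g) for g in background)
    if not query or not background:
        raise DataError("query and background must be non-empty")
    stray = query - background
    if stray:
        raise DataError(f"query genes missing from background: {sorted(stray)[:10]}")
    M, n = len(background), len(query)
    rows = []
    for name, members in sets.sets.items():
        inset = members & background
        overlap = sorted(inset & query)
        k, K = len(overlap), len(inset)
        # P(X >= k) for X ~ Hypergeom(M, K, n); k = 0 gives p = 1
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({
            "set": name, "description": sets.descriptions.get(name, ""),
            "overlap": k, "set_size": K, "query_size": n, "background_size": M,
            "p": min(p, 1.0), "overlap_genes": ",".join(overlap),
        })
    tab = pd.DataFrame(rows).set_index("set")
    tab["q"] = bh_fdr(tab["p"])
    tab["significant"] = tab["q"] < q_thresh
    return tab.sort_values(["q", "p"], kind="mergesort")


def intersect_gene_lists(a, b) -> dict:
    """Case- and whitespace-insensitive intersection of two gene lists."""
    sa = {_norm_symbol(g) for g in a}
    sb = {_norm_symbol(g) for g in b}
    overlap = sorted(sa & sb)
    return {"overlap": overlap, "n_overlap": len(overlap),
            "n_a": len(sa), "n_b": len(sb)}
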