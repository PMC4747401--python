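"""Hypergeometric over-representation of gene lists in pathway collections.

For a query list of n genes drawn from a universe of N genes, a pathway of
K genes containing x of the query is scored with the upper-tail
hypergeometric probability P(X >= x), the standard over-representation
test.  P-values are BH-adjusted across the collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .ranking import DirectionalGeneSet
from .rankproduct import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional declared universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if self.universe is not None and not members <= self.universe:
                raise ValueError(
                    f"gene set {name!r} has members outside the declared universe"
                )

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None):
        """Read standard GMT: name <tab> description <tab> member genes..."""
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
        if not sets:
            raise ValueError(f"no gene sets parsed from {path}")
        return cls(sets, frozenset(universe) if universe is not None else None)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (desc, members) in self.sets.items():
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_enrich(
    query: DirectionalGeneSet | Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    The universe is typically all genes measured on the platform.  Query
    genes outside the universe are dropped with a warning; pathway members
    outside the universe do not count toward set sizes.  Returns a table
    sorted by p with BH FDR across sets.
    """
    universe = frozenset(str(g) for g in universe)
    if not universe:
        raise ValueError("universe is empty")
    query_genes = query.genes if isinstance(query, DirectionalGeneSet) else set(query)
    dropped = query_genes - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes absent from the universe were dropped",
            stacklevel=2,
        )
    query_in = query_genes & universe
    if not query_in:
        raise ValueError("query has no genes in the universe")
    n_universe, n_query = len(universe), len(query_in)
    rows = []
    for name, (desc, members) in collection.sets.items():
        members_in = members & universe
        overlap = sorted(members_in & query_in)
        x = len(overlap)
        # P(X >= x) for X ~ Hypergeom(N, K, n); sf(x-1) includes the observed count
        p = float(hypergeom.sf(x - 1, n_universe, len(members_in), n_query))
        rows.append(
            {
                "set_name": name,
                "description": desc,
                "n_universe": n_universe,
                "n_set": len(members_in),
                "n_query": n_query,
                "n_overlap": x,
                "p_hyper": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p_hyper"])
    return (
        table.sort_values(["p_hyper", "set_name"], kind="stable")
        .reset_index(drop=True)
        [
            [
                "set_name",
                "description",
                "n_universe",
                "n_set",
                "n_query",
                "n_overlap",
                "p_hyper",
                "fdr",
                "overlap_genes",
            ]
        ]
    )
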