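"""FC/AD change statistics and top-N directional gene lists.

Two ranking statistics are computed between the arithmetic means of two
sample groups on the linear scale:

* fold change ``FC_i = mean_A(i) / mean_B(i)`` — up if > 1, down if < 1;
* average difference ``AD_i = mean_A(i) - mean_B(i)`` — up if > 0, down if < 0.

Group A is by convention the resistant/treated member of a comparison, so
"up" always means higher expression in the resistant or treated state.

Because a descending sort of the signed statistic alone cannot produce a
mixed up/down top list, genes are ranked by symmetric change magnitude by
default: ``max(FC, 1/FC)`` for FC and ``|AD|`` for AD.  Ranking by the
signed statistic is available via ``rank_by="signed"``.

Small-replicate cell-line designs (2-3 technical replicates per condition)
are the intended regime: variance-based statistics have little power there,
which is why plain FC/AD ranking is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import LINEAR, ExpressionMatrix
from .preprocess import delog

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class DirectionalGeneSet:
    """A set of genes each labeled with a deregulation direction.

    The universal currency for BD/IP/ID/CRG lists: ``members`` maps
    gene_id -> "up" | "down" (each gene appears once).
    """

    label: str
    members: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.members.items() if d not in (UP, DOWN)}
        if bad:
            raise ValueError(f"directions must be 'up'/'down'; got {bad}")

    @property
    def genes(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.members), "direction": list(self.members.values())}
        )

    @classmethod
    def from_frame(cls, label: str, frame: pd.DataFrame) -> "DirectionalGeneSet":
        return cls(label, dict(zip(frame["gene_id"].astype(str), frame["direction"])))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str | None = None) -> "DirectionalGeneSet":
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        return cls.from_frame(label or str(path), frame)


@dataclass
class RankedGeneList:
    """Genes ordered by a change statistic with per-gene direction calls.

    ``table`` is indexed by gene_id with columns ``stat`` (signed FC or
    AD), ``magnitude`` (symmetric ranking key), ``direction`` and ``rank``
    (1..n, by decreasing magnitude, ties broken by gene id).
    """

    method: str  # "FC" | "AD"
    table: pd.DataFrame
    group_a_label: str
    group_b_label: str
    rank_by: str = "magnitude"

    def __len__(self) -> int:
        return len(self.table)

    def top_n(self, n: int, label: str | None = None) -> DirectionalGeneSet:
        return top_n(self, n, label=label)


def _group_means(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[pd.Series, pd.Series, ExpressionMatrix]:
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both sample groups must be non-empty")
    if matrix.scale != LINEAR:
        matrix = delog(matrix)
    mean_a = matrix.values[group_a].mean(axis=1)
    mean_b = matrix.values[group_b].mean(axis=1)
    return mean_a, mean_b, matrix


def _build_list(
    method: str,
    stat: pd.Series,
    magnitude: pd.Series,
    direction: pd.Series,
    group_a_label: str,
    group_b_label: str,
    rank_by: str,
) -> RankedGeneList:
    key = magnitude if rank_by == "magnitude" else stat
    table = pd.DataFrame(
        {"stat": stat, "magnitude": magnitude, "direction": direction, "_key": key}
    )
    # stable tie-break by gene id: pre-sort on the index, then stable-sort on key
    table = table.sort_index().sort_values(by="_key", ascending=False, kind="stable")
    table.index.name = "gene_id"
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.drop(columns="_key")
    return RankedGeneList(
        method=method,
        table=table,
        group_a_label=group_a_label,
        group_b_label=group_b_label,
        rank_by=rank_by,
    )


def compute_fc(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    group_a_label: str = "A",
    group_b_label: str = "B",
    floor: float | None = None,
    rank_by: str = "magnitude",
) -> RankedGeneList:
    """Fold change of group-A over group-B mean expression per gene.

    The matrix is de-logged if needed; group means must be positive
    (optionally floor individual values at ``floor`` first).  Direction is
    up for FC > 1, down for FC < 1, none for FC == 1.
    """
    mean_a, mean_b, matrix = _group_means(matrix, group_a, group_b)
    if floor is not None:
        vals = matrix.values.clip(lower=floor)
        mean_a = vals[list(group_a)].mean(axis=1)
        mean_b = vals[list(group_b)].mean(axis=1)
    if (mean_b <= 0).any():
        offenders = mean_b.index[mean_b <= 0][:3].tolist()
        raise ValueError(f"non-positive group-B mean for genes {offenders}")
    if (mean_a <= 0).any():
        offenders = mean_a.index[mean_a <= 0][:3].tolist()
        raise ValueError(f"non-positive group-A mean for genes {offenders}")
    fc = mean_a / mean_b
    direction = pd.Series(NONE, index=fc.index)
    direction[fc > 1] = UP
    direction[fc < 1] = DOWN
    magnitude = np.maximum(fc, 1.0 / fc)
    return _build_list("FC", fc, magnitude, direction, group_a_label, group_b_label, rank_by)


def compute_ad(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    group_a_label: str = "A",
    group_b_label: str = "B",
    rank_by: str = "magnitude",
) -> RankedGeneList:
    """Average difference mean_A - mean_B per gene (linear scale).

    Direction is up for AD > 0, down for AD < 0, none for AD == 0.
    """
    mean_a, mean_b, _ = _group_means(matrix, group_a, group_b)
    ad = mean_a - mean_b
    direction = pd.Series(NONE, index=ad.index)
    direction[ad > 0] = UP
    direction[ad < 0] = DOWN
    return _build_list(
        "AD", ad, ad.abs(), direction, group_a_label, group_b_label, rank_by
    )


def top_n(ranked: RankedGeneList, n: int, label: str | None = None) -> DirectionalGeneSet:
    """The n genes with largest change magnitude, with their directions.

    Genes with direction ``none`` carry no deregulation call and are
    excluded before selection; asking for more genes than are directional
    is an error.
    """
    directional = ranked.table[ranked.table["direction"] != NONE]
    if n > len(directional):
        raise ValueError(
            f"requested top {n} but only {len(directional)} directional genes"
        )
    if n <= 0:
        raise ValueError("n must be positive")
    chosen = directional.iloc[:n]
    return DirectionalGeneSet(
        label=label or f"{ranked.method}_top{n}",
        members=dict(zip(chosen.index.astype(str), chosen["direction"])),
    )


_DESIGNS = {"BD", "IP", "ID"}


def define_gene_class(
    matrix: ExpressionMatrix,
    design: str,
    drug: str,
    time_h: float | None,
    method: str,
    n: int,
    rank_by: str = "magnitude",
    label: str | None = None,
) -> DirectionalGeneSet:
    """Select a BD, IP or ID gene list from a cell-line experiment.

    * BD: untreated resistant vs untreated parental cells;
    * IP: drug-treated parental at ``time_h`` vs untreated parental;
    * ID: drug-treated resistant vs drug-treated parental at ``time_h``.

    Group A is always the resistant/treated member, so "up" means higher
    in the resistant or treated state.  ``method`` is "fc" or "ad".
    """
    design = design.upper()
    if design not in _DESIGNS:
        raise ValueError(f"design must be one of {_DESIGNS}, got {design!r}")
    if design in ("IP", "ID") and time_h is None:
        raise ValueError(f"{design} lists require a treatment time")
    if design == "BD":
        sel_a = dict(resistance_status="resistant", drug="none")
        sel_b = dict(resistance_status="parental", drug="none")
    elif design == "IP":
        sel_a = dict(resistance_status="parental", drug=drug, treatment_time_h=time_h)
        sel_b = dict(resistance_status="parental", drug="none")
    else:  # ID
        sel_a = dict(resistance_status="resistant", drug=drug, treatment_time_h=time_h)
        sel_b = dict(resistance_status="parental", drug=drug, treatment_time_h=time_h)
    group_a = matrix.sample_ids(**sel_a)
    group_b = matrix.sample_ids(**sel_b)
    for name, group, sel in (("A", group_a, sel_a), ("B", group_b, sel_b)):
        if not group:
            raise ValueError(
                f"{design} design: no samples matching group {name} selector {sel}"
            )
    fn = compute_fc if method.lower() == "fc" else compute_ad
    ranked = fn(
        matrix,
        group_a,
        group_b,
        group_a_label=str(sel_a),
        group_b_label=str(sel_b),
        rank_by=rank_by,
    )
    suffix = "" if design == "BD" else f"_{time_h:g}"
    default_label = f"{design}{suffix}/{method.upper()}/{drug}"
    return top_n(ranked, n, label=label or default_label)


def two_drug_intersection(
    set1: DirectionalGeneSet, set2: DirectionalGeneSet, label: str | None = None
) -> DirectionalGeneSet:
    """Genes present in both sets with the same direction (BD_two / ID_two)."""
    members = {
        g: d
        for g, d in set1.members.items()
        if set2.members.get(g) == d
    }
    return DirectionalGeneSet(label or f"{set1.label}&{set2.label}", members)


@dataclass
class ExpressionBiasReport:
    """Mean expression of genes detected exclusively by one ranking method.

    Quantifies the selection bias of the two statistics: AD favours genes
    expressed at high levels (large absolute differences at modest ratios),
    FC favours low-expressed genes where small absolute changes give large
    ratios.
    """

    exclusive_x: list[str]
    exclusive_y: list[str]
    label_x: str
    label_y: str
    mean_expr_x: dict[str, float]  # group label -> mean over exclusive_x genes
    mean_expr_y: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, excl, means in (
            (self.label_x, self.exclusive_x, self.mean_expr_x),
            (self.label_y, self.exclusive_y, self.mean_expr_y),
        ):
            row = {"set": label, "n_exclusive": len(excl)}
            row.update({f"mean_{k}": v for k, v in means.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def expression_bias_report(
    set_x: DirectionalGeneSet,
    set_y: DirectionalGeneSet,
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    group_a_label: str = "A",
    group_b_label: str = "B",
) -> ExpressionBiasReport:
    """Compare mean expression of method-exclusive genes from one comparison.

    ``set_x`` and ``set_y`` should be the same comparison ranked by two
    different statistics (typically FC and AD).  For the genes exclusive
    to each, the report carries the average of the linear-scale group-mean
    expression in both sample groups.
    """
    if matrix.scale != LINEAR:
        matrix = delog(matrix)
    excl_x = sorted(set_x.genes - set_y.genes)
    excl_y = sorted(set_y.genes - set_x.genes)

    def group_means(genes: list[str]) -> dict[str, float]:
        if not genes:
            return {group_a_label: float("nan"), group_b_label: float("nan")}
        sub = matrix.values.loc[genes]
        return {
            group_a_label: float(sub[list(group_a)].mean(axis=1).mean()),
            group_b_label: float(sub[list(group_b)].mean(axis=1).mean()),
        }

    return ExpressionBiasReport(
        exclusive_x=excl_x,
        exclusive_y=excl_y,
        label_x=set_x.label,
        label_y=set_y.label,
        mean_expr_x=group_means(excl_x),
        mean_expr_y=group_means(excl_y),
    )
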