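"""Clinically relevant drug-resistance gene (CRG) derivation.

CRGs are DEGs between pre-chemotherapy tumour samples of non-responders
and responders.  Because chemotherapy is given in combination regimens,
single-drug attribution relies on a set-logic consequence of the
no-antagonism assumption: if two regimens share one or several drugs, the
direction-consistent overlap of their CRG lists is the CRG set of the
shared drug(s).  The code implements that conclusion as a direction-aware
intersection; antagonistic drug-drug interaction is assumed away.

Orientation convention: "up" means higher expression in non-responders
(the resistant phenotype), matching the cell-line lists where "up" means
higher in the resistant line, so the two domains can be scored for
consistency directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .ranking import DirectionalGeneSet
from .rankproduct import deg_filter


@dataclass
class RegimenDEG:
    """A clinical DEG list with the drugs of the regimen that produced it."""

    regimen_label: str
    drugs: frozenset[str]
    deg: DirectionalGeneSet
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drugs = frozenset(self.drugs)
        if not self.drugs:
            raise ValueError(f"regimen {self.regimen_label!r} lists no drugs")


@dataclass
class CRGSet:
    """CRGs attributed to the drugs shared by the contributing regimens.

    ``support`` records, per member gene, the contributing regimens (or
    evidence tiers); ``conflicts`` holds genes present in every list but
    excluded for direction disagreement.
    """

    shared_drugs: frozenset[str]
    members: DirectionalGeneSet
    support: dict[str, list[str]] = field(default_factory=dict)
    conflicts: dict[str, dict[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def intersect_regimens(regimens: Sequence[RegimenDEG]) -> CRGSet:
    """Direction-consistent intersection of clinical DEG lists.

    Members are genes appearing with the same direction in every regimen's
    list; they are attributed to the intersection of the regimens' drug
    sets.  Genes found in every list but with conflicting directions are
    excluded and reported in ``conflicts``.  Genes measured in only a
    subset of the lists are excluded (a direction cannot be confirmed
    where unmeasured).
    """
    if len(regimens) < 2:
        raise ValueError("need at least two regimens to attribute shared drugs")
    shared_drugs = frozenset.intersection(*(r.drugs for r in regimens))
    if not shared_drugs:
        raise ValueError(
            "regimens share no drug; the shared-drug inference is undefined"
        )
    common = set.intersection(*(r.deg.genes for r in regimens))
    members: dict[str, str] = {}
    conflicts: dict[str, dict[str, str]] = {}
    support: dict[str, list[str]] = {}
    for gene in sorted(common):
        directions = {r.regimen_label: r.deg.members[gene] for r in regimens}
        if len(set(directions.values())) == 1:
            members[gene] = next(iter(directions.values()))
            support[gene] = [r.regimen_label for r in regimens]
        else:
            conflicts[gene] = directions
    label = "CRG_" + "/".join(sorted(shared_drugs))
    return CRGSet(
        shared_drugs=shared_drugs,
        members=DirectionalGeneSet(label, members),
        support=support,
        conflicts=conflicts,
    )


def tiered_crg(
    discovery: pd.DataFrame,
    confirmations: Sequence[pd.DataFrame],
    fdr_discovery: float = 0.2,
    p_confirm: float = 0.05,
    drugs: frozenset[str] | set[str] = frozenset(),
    label: str = "CRG",
) -> CRGSet:
    """Two-tier CRG call: FDR in a discovery cohort, p in confirmation cohorts.

    Genes must pass ``fdr <= fdr_discovery`` in the discovery DEG table and
    ``p <= p_confirm`` with the same direction in every confirmation table.
    With no confirmation tables the discovery genes are returned with an
    ``unconfirmed`` support tag.
    """
    disc = deg_filter(discovery, fdr_max=fdr_discovery, label=f"{label}:discovery")
    members: dict[str, str] = {}
    support: dict[str, list[str]] = {}
    conflicts: dict[str, dict[str, str]] = {}
    if not confirmations:
        members = dict(disc.members)
        support = {g: ["unconfirmed"] for g in members}
    else:
        confirm_sets = [
            deg_filter(t, p_max=p_confirm, label=f"{label}:confirm{i}")
            for i, t in enumerate(confirmations, start=1)
        ]
        for gene, direction in disc.members.items():
            tiers = [f"discovery(fdr<={fdr_discovery})"]
            directions_seen = {disc.label: direction}
            ok = True
            for cset in confirm_sets:
                if gene not in cset:
                    ok = False
                    break
                directions_seen[cset.label] = cset.members[gene]
                if cset.members[gene] != direction:
                    ok = False
                    conflicts[gene] = directions_seen
                    break
                tiers.append(f"{cset.label}(p<={p_confirm})")
            if ok:
                members[gene] = direction
                support[gene] = tiers
    return CRGSet(
        shared_drugs=frozenset(drugs),
        members=DirectionalGeneSet(label, members),
        support=support,
        conflicts=conflicts,
    )


def id_clinical(
    post_chemo_table: pd.DataFrame, fdr_max: float = 0.1, label: str = "ID_clinical"
) -> DirectionalGeneSet:
    """ID_clinical genes: post-chemotherapy responder/non-responder DEGs.

    A thin threshold wrapper (default FDR <= 0.1) over a DEG table from a
    post-chemotherapy cohort comparison, oriented so "up" means higher in
    non-responders.
    """
    return deg_filter(post_chemo_table, fdr_max=fdr_max, label=label)
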