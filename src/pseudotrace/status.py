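"""Gene and heterodimeric-receptor functional status.

A gene is a pseudogene iff its lesion report contains at least one
inactivating record; ``unknown`` is reserved for taxa that were never
scanned.  TAS1R-type receptors are obligate heterodimers, so loss of
integrity of either component gene inactivates the receptor: a receptor is
``nonfunctional`` iff any component is a pseudogene, ``functional`` iff all
components are intact, and ``unknown`` otherwise (an unknown component never
improves the call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .lesions import LesionReport, MutationRecord

INTACT = "intact"
PSEUDOGENE = "pseudogene"
UNKNOWN = "unknown"

FUNCTIONAL = "functional"
NONFUNCTIONAL = "nonfunctional"


@dataclass
class GeneStatus:
    taxon: str
    gene: str
    status: str
    supporting: list[MutationRecord] = field(default_factory=list)

    @classmethod
    def unknown(cls, taxon: str, gene: str) -> "GeneStatus":
        return cls(taxon, gene, UNKNOWN)

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "gene": self.gene,
            "status": self.status,
            "supporting": [r.to_dict() for r in self.supporting],
        }


def call_gene_status(report: LesionReport) -> GeneStatus:
    """Pseudogene iff at least one inactivating record; else intact."""
    inact = report.inactivating_records
    return GeneStatus(
        taxon=report.taxon,
        gene=report.gene,
        status=PSEUDOGENE if inact else INTACT,
        supporting=list(inact),
    )


@dataclass(frozen=True)
class ReceptorDefinition:
    name: str
    genes: tuple[str, ...]


@dataclass
class ReceptorStatus:
    name: str
    genes: tuple[str, ...]
    component_status: dict[str, str]
    functional: str

    def to_dict(self) -> dict:
        return {
            "receptor": self.name,
            "genes": list(self.genes),
            "component_status": dict(self.component_status),
            "functional": self.functional,
        }


def call_receptor_status(
    defn: ReceptorDefinition,
    statuses: Mapping[str, Optional[GeneStatus]],
) -> ReceptorStatus:
    """Combine component-gene calls under the heterodimer rule.

    ``statuses`` maps gene name to a :class:`GeneStatus` (or ``None`` /
    missing for an unscanned gene, treated as unknown).  Component order is
    irrelevant.
    """
    comp: dict[str, str] = {}
    for gene in defn.genes:
        gs = statuses.get(gene)
        comp[gene] = gs.status if gs is not None else UNKNOWN
    if any(s == PSEUDOGENE for s in comp.values()):
        fn = NONFUNCTIONAL
    elif all(s == INTACT for s in comp.values()):
        fn = FUNCTIONAL
    else:
        fn = UNKNOWN
    return ReceptorStatus(defn.name, tuple(defn.genes), comp, fn)
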