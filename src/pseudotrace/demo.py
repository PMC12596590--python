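"""Worked example: umami-receptor pseudogenization in Lyncodontini weasels.

The published survey of the *TAS1R1* (umami, with TAS1R3) and *TAS1R3* genes
in the Patagonian weasel (*Lyncodon patagonicus*) and lesser grison
(*Galictis cuja*) describes six inactivating lesions against jointly aligned
functional references (*Canis familiaris*, *Vormela peregusna*, *Ictonyx
striatus*), all in per-exon reference coordinates:

* *TAS1R1* exon 3: C→T at 295 bp creating a TGA stop at 295–297 (weasel);
* *TAS1R1* exon 4: C→T at 10 bp creating a TAG stop at 10–12 (grison);
* *TAS1R1* exon 4: a long (>210 bp; 213 bp here) insertion between 57 and
  58 bp carrying an in-frame TAA (weasel);
* *TAS1R1* exon 6: a shared 1-bp insertion between 693 and 694 bp whose
  shifted frame first stops at TAG 746–748 (both species);
* *TAS1R1* exon 6: a shared 1-bp insertion between 823 and 824 bp with no
  premature stop before the CDS end (both species);
* *TAS1R3* exon 3: C/T→G at 690 bp creating a TAG stop at 688–690 at a
  site where the references themselves are polymorphic (weasel).

The original sequences are not redistributed here; this module rebuilds the
same lesion geometry over a synthetic functional background (random sense
codons, with the lesion-bearing neighbourhoods pinned so that every
published coordinate, triplet and count is reproduced exactly).  The shared
frameshifts map onto the stem lineage of Lyncodontini of a dated
Ictonychinae tree whose two relevant node ages are 3.0 and 9.5 Mya (other
ages are placeholders), which brackets the loss of the TAS1R1–TAS1R3
receptor between those ages and predicts nonfunctionality for the unsampled
greater grison (*Galictis vittata*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import STOP_CODONS, ExonAlignment, ExonSpec, GeneModel
from .phylo import TimeTree, parse_time_tree
from .simulate import SENSE_CODONS, LesionSpec, plant_fixture_mutations
from .status import ReceptorDefinition

REFERENCE_TAXA = ("Canis_familiaris", "Vormela_peregusna", "Ictonyx_striatus")
TARGET_TAXA = ("Lyncodon_patagonicus", "Galictis_cuja")
WEASEL = "Lyncodon_patagonicus"
GRISON = "Galictis_cuja"
UNSAMPLED = "Galictis_vittata"

TAS1R1_EXONS = [267, 156, 297, 300, 118, 935]
TAS1R3_EXONS = [219, 144, 720, 300, 180, 390]

#: dated Ictonychinae phylogeny (ages in Mya): the Lyncodontini crown at 3.0
#: and its parent at 9.5 are the two constrained ages; the rest, and the dog
#: outgroup at 45, are placeholders.
DEMO_NEWICK = (
    "(Canis_familiaris:45.0,"
    "((Lyncodon_patagonicus:3.0,(Galictis_cuja:1.5,Galictis_vittata:1.5)"
    "Galictis:1.5)Lyncodontini:6.5,"
    "(Ictonyx_striatus:6.0,Vormela_peregusna:6.0)IctonyxVormela:3.5)"
    "Ictonychinae:35.5)Caniformia;"
)

RECEPTORS = {
    "TAS1R1-TAS1R3": ReceptorDefinition("TAS1R1-TAS1R3", ("TAS1R1", "TAS1R3")),
    "TAS1R2-TAS1R3": ReceptorDefinition("TAS1R2-TAS1R3", ("TAS1R2", "TAS1R3")),
}

# 213-bp insertion: 12-bp lead-in, an in-frame TAA, then sense codons.
_LONG_INSERTION = (
    "GTGCTGAGCGCC" + "TAA"
    + "".join(["GCA", "GCC", "AGC", "CAG", "GAG", "CCA"] * 11)
)
assert len(_LONG_INSERTION) == 213

TAS1R1_LESIONS = [
    LesionSpec("substitution", "exon3", 295, (WEASEL,), seq="T"),
    LesionSpec("substitution", "exon4", 10, (GRISON,), seq="T"),
    LesionSpec("insertion", "exon4", 57, (WEASEL,), seq=_LONG_INSERTION),
    LesionSpec("insertion", "exon6", 693, (WEASEL, GRISON), seq="A"),
    LesionSpec("insertion", "exon6", 823, (WEASEL, GRISON), seq="C"),
]

TAS1R3_LESIONS = [
    LesionSpec("substitution", "exon3", 690, (WEASEL,), seq="G"),
]

#: reference-site polymorphism at the TAS1R3 exon-3 site: dog and striped
#: polecat carry C, marbled polecat carries T; the codon stays Tyr either way.
TAS1R3_REF_OVERRIDES = {
    ("exon3", 690): {"Vormela_peregusna": "T"},
}


def _random_sense_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx) + "TGA"


def _patch(cds: str, start0: int, piece: str) -> str:
    return cds[:start0] + piece + cds[start0 + len(piece):]


def _strip_t(cds: str, start0: int, end0: int) -> str:
    """Replace T with C over [start0, end0); removing T cannot create stops."""
    zone = cds[start0:end0].replace("T", "C")
    return cds[:start0] + zone + cds[end0:]


def _model(gene: str, lengths: list[int]) -> GeneModel:
    exons = []
    phase = 0
    for i, L in enumerate(lengths):
        exons.append(ExonSpec(f"exon{i + 1}", L, phase))
        phase = (phase + L) % 3
    return GeneModel(gene, exons)


def build_tas1r1_reference(seed: int = 0) -> tuple[str, GeneModel]:
    """Synthetic functional TAS1R1 with the lesion neighbourhoods pinned."""
    model = _model("TAS1R1", TAS1R1_EXONS)
    rng = np.random.default_rng([seed, 11])
    cds = _random_sense_cds(model.n_codons - 1, rng)
    off3 = model.global_ref_index("exon3", 1) - 1
    off4 = model.global_ref_index("exon4", 1) - 1
    off6 = model.global_ref_index("exon6", 1) - 1
    cds = _patch(cds, off3 + 294, "CGA")   # exon3 295-297; C→T gives TGA
    cds = _patch(cds, off4 + 9, "CAG")     # exon4 10-12;   C→T gives TAG
    # exon 6: keep 693..932 free of T so the only shifted-frame stop after
    # the 693/694 frameshift is the TAG pinned at 746-748, and the 823/824
    # frameshift meets no stop before the CDS end
    cds = _strip_t(cds, off6 + 692, off6 + 932)
    cds = _patch(cds, off6 + 745, "TAG")   # read as a stop only in +1 frame
    _assert_functional(cds)
    return cds, model


def build_tas1r3_reference(seed: int = 0) -> tuple[str, GeneModel]:
    """Synthetic functional TAS1R3; exon-3 688-690 pinned to Tyr (TAC)."""
    model = _model("TAS1R3", TAS1R3_EXONS)
    rng = np.random.default_rng([seed, 13])
    cds = _random_sense_cds(model.n_codons - 1, rng)
    off3 = model.global_ref_index("exon3", 1) - 1
    cds = _patch(cds, off3 + 687, "TAC")   # 688-690; C/T→G gives TAG
    _assert_functional(cds)
    return cds, model


def _assert_functional(cds: str) -> None:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    assert all(c not in STOP_CODONS for c in codons[:-1])
    assert codons[-1] in STOP_CODONS


@dataclass
class DemoBundle:
    models: dict[str, GeneModel]
    alignments: dict[str, list[ExonAlignment]]
    roles: dict[str, str]
    newick: str
    tree: TimeTree
    receptors: dict[str, ReceptorDefinition] = field(default_factory=dict)
    #: gene statuses taken from prior work rather than scanned here
    assumed_intact: frozenset = frozenset()


def build_bundle(seed: int = 0) -> DemoBundle:
    """Assemble the full demo: both genes, both targets, the dated tree."""
    cds1, model1 = build_tas1r1_reference(seed)
    cds3, model3 = build_tas1r3_reference(seed)
    aln1 = plant_fixture_mutations(
        cds1, model1, TAS1R1_LESIONS, REFERENCE_TAXA, target_taxa=TARGET_TAXA
    )
    aln3 = plant_fixture_mutations(
        cds3, model3, TAS1R3_LESIONS, REFERENCE_TAXA, target_taxa=TARGET_TAXA,
        reference_overrides=TAS1R3_REF_OVERRIDES,
    )
    roles = {t: "reference" for t in REFERENCE_TAXA}
    roles.update({t: "target" for t in TARGET_TAXA})
    return DemoBundle(
        models={"TAS1R1": model1, "TAS1R3": model3},
        alignments={"TAS1R1": aln1, "TAS1R3": aln3},
        roles=roles,
        newick=DEMO_NEWICK,
        tree=parse_time_tree(DEMO_NEWICK),
        receptors=dict(RECEPTORS),
        assumed_intact=frozenset({(GRISON, "TAS1R3")}),
    )
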