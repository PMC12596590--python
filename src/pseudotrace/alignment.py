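"""Exon-wise CDS alignment model with a reference-anchored coordinate system.

The central objects are:

* :class:`ExonAlignment` — one aligned exon, rows tagged as ``reference`` or
  ``target``.  Coordinates are always expressed against the reference rows,
  1-based, counted from the 5' end of each exon separately.
* :class:`GeneModel` — exon order, reference lengths and phases; the reading
  frame is continuous across exon junctions, so codons may span junctions.
* :class:`CoordinateMap` — per alignment column, either a reference position
  or an insertion slot "between p and p+1" with an ordinal offset.  A column
  counts as a reference position if ANY reference row is non-gap there (the
  permissive reading when jointly-aligned references disagree in gap
  pattern); columns gapped in all reference rows are insertion slots
  attached to the nearest preceding reference position.
* :class:`GeneView` — the concatenation of all exons of a gene, with global
  reference coordinates, per-taxon gap-stripped CDS extraction and a map
  back to (exon, reference position / insertion slot).

The gap character is fixed to ``-`` (``.`` is rejected); input residue case
is normalised to upper case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    ModelConsistencyError,
    RoleError,
)

#: IUPAC nucleotide ambiguity codes, expanded to plain bases.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"
ALPHABET = frozenset(IUPAC) | {GAP}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

ROLE_REFERENCE = "reference"
ROLE_TARGET = "target"


def expand(residue: str) -> frozenset[str]:
    """Expand a (possibly ambiguous) residue to its set of plain bases."""
    try:
        return IUPAC[residue]
    except KeyError:
        raise AlphabetError(f"unknown residue symbol {residue!r}") from None


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class RefPosition:
    """A 1-based reference coordinate within one exon."""

    exon_id: str
    pos: int

    def key(self) -> str:
        return str(self.pos)

    def sort_pos(self) -> tuple[float, int]:
        return (float(self.pos), 0)


@dataclass(frozen=True, order=True)
class InsertionSlot:
    """An insertion slot "between `after` and `after`+1"; offset orders
    multiple all-reference-gap columns sharing the same anchor."""

    exon_id: str
    after: int
    offset: int = 1

    def key(self) -> str:
        return f"{self.after}^{self.after + 1}"

    def sort_pos(self) -> tuple[float, int]:
        return (self.after + 0.5, self.offset)


@dataclass(frozen=True, order=True)
class RefInterval:
    """A closed interval of reference positions within one exon (deletions)."""

    exon_id: str
    start: int
    end: int

    def key(self) -> str:
        return f"{self.start}..{self.end}"

    def sort_pos(self) -> tuple[float, int]:
        return (float(self.start), 0)


Location = Union[RefPosition, InsertionSlot, RefInterval]


def location_to_dict(loc: Location) -> dict:
    if isinstance(loc, RefPosition):
        return {"kind": "position", "exon": loc.exon_id, "pos": loc.pos}
    if isinstance(loc, InsertionSlot):
        return {"kind": "slot", "exon": loc.exon_id, "after": loc.after}
    return {"kind": "interval", "exon": loc.exon_id, "start": loc.start, "end": loc.end}


def location_from_dict(d: Mapping) -> Location:
    kind = d["kind"]
    if kind == "position":
        return RefPosition(d["exon"], int(d["pos"]))
    if kind == "slot":
        return InsertionSlot(d["exon"], int(d["after"]))
    if kind == "interval":
        return RefInterval(d["exon"], int(d["start"]), int(d["end"]))
    raise ValueError(f"unknown location kind {kind!r}")


# ---------------------------------------------------------------------------
# exon alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRow:
    taxon: str
    role: str
    seq: str


class ExonAlignment:
    """One aligned exon block; validates shape, alphabet and roles on load."""

    def __init__(self, exon_id: str, rows: Sequence[AlignedRow]):
        self.exon_id = exon_id
        self.rows = list(rows)
        if not self.rows:
            raise AlignmentShapeError(f"{exon_id}: empty alignment")
        n = len(self.rows[0].seq)
        for row in self.rows:
            if len(row.seq) != n:
                raise AlignmentShapeError(
                    f"{exon_id}: row {row.taxon!r} has {len(row.seq)} columns, "
                    f"expected {n}"
                )
            bad = set(row.seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"{exon_id}: row {row.taxon!r} contains {sorted(bad)!r}"
                )
            if row.role not in (ROLE_REFERENCE, ROLE_TARGET):
                raise RoleError(f"{exon_id}: {row.taxon!r} has role {row.role!r}")
        roles = {r.role for r in self.rows}
        if ROLE_REFERENCE not in roles or ROLE_TARGET not in roles:
            raise RoleError(
                f"{exon_id}: need at least one reference and one target row"
            )
        names = [r.taxon for r in self.rows]
        if len(set(names)) != len(names):
            raise RoleError(f"{exon_id}: duplicate taxon names")
        self.n_columns = n
        self._by_taxon = {r.taxon: r for r in self.rows}

    def row(self, taxon: str) -> AlignedRow:
        return self._by_taxon[taxon]

    @property
    def taxa(self) -> list[str]:
        return [r.taxon for r in self.rows]

    @property
    def reference_rows(self) -> list[AlignedRow]:
        return [r for r in self.rows if r.role == ROLE_REFERENCE]

    @property
    def target_rows(self) -> list[AlignedRow]:
        return [r for r in self.rows if r.role == ROLE_TARGET]


def load_exon_alignment(
    path: str | Path, exon_id: str, roles: Mapping[str, str]
) -> ExonAlignment:
    """Load one aligned FASTA exon file; every record must have a role."""
    path = Path(path)
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in roles:
            raise RoleError(f"{path.name}: taxon {rec.id!r} has no role")
        rows.append(AlignedRow(rec.id, roles[rec.id], str(rec.seq).upper()))
    if not rows:
        raise AlignmentShapeError(f"{path.name}: no sequences")
    return ExonAlignment(exon_id, rows)


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonSpec:
    exon_id: str
    length: int
    phase_in: int


@dataclass(frozen=True)
class NativeStop:
    exon_id: str
    start: int  # 1-based reference position of the stop codon's first base


class GeneModel:
    """Exon order, reference lengths, phases and the native terminal stop.

    Invariants enforced on construction: reference lengths sum to a multiple
    of 3; each exon's ``phase_in`` chains as
    ``(phase_in[k] + length[k]) mod 3``; the native stop is the final codon
    of the concatenated reference CDS (the last exon must hold all 3 bases).
    """

    def __init__(self, gene_name: str, exons: Sequence[ExonSpec],
                 native_stop: NativeStop | None = None):
        self.gene_name = gene_name
        self.exons = list(exons)
        if not self.exons:
            raise ModelConsistencyError(f"{gene_name}: no exons")
        total = sum(e.length for e in self.exons)
        if total % 3:
            raise ModelConsistencyError(
                f"{gene_name}: total reference length {total} not divisible by 3"
            )
        phase = 0
        for e in self.exons:
            if e.length <= 0:
                raise ModelConsistencyError(f"{gene_name}: exon {e.exon_id} length {e.length}")
            if e.phase_in != phase:
                raise ModelConsistencyError(
                    f"{gene_name}: exon {e.exon_id} phase_in {e.phase_in}, expected {phase}"
                )
            phase = (phase + e.length) % 3
        last = self.exons[-1]
        if last.length < 3:
            raise ModelConsistencyError(
                f"{gene_name}: last exon shorter than one codon"
            )
        derived = NativeStop(last.exon_id, last.length - 2)
        if native_stop is None:
            native_stop = derived
        elif native_stop != derived:
            raise ModelConsistencyError(
                f"{gene_name}: native_stop {native_stop} is not the final codon "
                f"of the concatenated CDS ({derived})"
            )
        self.native_stop = native_stop
        self.total_length = total
        self.n_codons = total // 3
        # cumulative reference length before each exon
        self._cum: dict[str, int] = {}
        c = 0
        for e in self.exons:
            self._cum[e.exon_id] = c
            c += e.length

    def exon(self, exon_id: str) -> ExonSpec:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise ModelConsistencyError(f"{self.gene_name}: unknown exon {exon_id!r}")

    def exon_index(self, exon_id: str) -> int:
        for i, e in enumerate(self.exons):
            if e.exon_id == exon_id:
                return i
        raise ModelConsistencyError(f"{self.gene_name}: unknown exon {exon_id!r}")

    def global_ref_index(self, exon_id: str, pos: int) -> int:
        """1-based position in the concatenated reference CDS."""
        return self._cum[exon_id] + pos

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_name,
            "exons": [
                {"id": e.exon_id, "length": e.length, "phase_in": e.phase_in}
                for e in self.exons
            ],
            "native_stop": {"exon": self.native_stop.exon_id,
                            "start": self.native_stop.start},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneModel":
        exons = [ExonSpec(x["id"], int(x["length"]), int(x["phase_in"]))
                 for x in d["exons"]]
        ns = d.get("native_stop")
        native = NativeStop(ns["exon"], int(ns["start"])) if ns else None
        return cls(d["gene"], exons, native)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# coordinate map
# ---------------------------------------------------------------------------

@dataclass
class CoordinateMap:
    """Column → reference position / insertion slot, for one exon."""

    exon_id: str
    entries: list[Location] = field(default_factory=list)

    @property
    def ref_length(self) -> int:
        return sum(1 for e in self.entries if isinstance(e, RefPosition))

    def column_of(self, pos: int) -> int:
        for i, e in enumerate(self.entries):
            if isinstance(e, RefPosition) and e.pos == pos:
                return i
        raise ModelConsistencyError(
            f"{self.exon_id}: reference position {pos} not in map"
        )


def build_coordinate_map(aln: ExonAlignment) -> CoordinateMap:
    """Number alignment columns against the reference rows.

    A column is a reference position iff at least one reference-role row is
    non-gap in it; all-reference-gap columns become insertion slots attached
    to the nearest preceding reference position (``between 0 and 1`` if none
    precedes), with offsets counting 1..k along a run.
    """
    refs = aln.reference_rows
    entries: list[Location] = []
    pos = 0
    offset = 0
    for col in range(aln.n_columns):
        if any(r.seq[col] != GAP for r in refs):
            pos += 1
            offset = 0
            entries.append(RefPosition(aln.exon_id, pos))
        else:
            offset += 1
            entries.append(InsertionSlot(aln.exon_id, pos, offset))
    return CoordinateMap(aln.exon_id, entries)


# ---------------------------------------------------------------------------
# gene view (concatenation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalColumn:
    exon_idx: int
    exon_id: str
    col: int            # column within the exon alignment
    entry: Location


class GeneView:
    """Concatenated per-taxon view of a gene with a global reading frame.

    Reference coordinates are global 1-based indices into the concatenated
    reference CDS; the codon containing global index ``g`` is
    ``(g - 1) // 3`` and codons may span exon junctions.
    """

    def __init__(self, alignments: Sequence[ExonAlignment], model: GeneModel):
        if len(alignments) != len(model.exons):
            raise ModelConsistencyError(
                f"{model.gene_name}: {len(alignments)} alignments for "
                f"{len(model.exons)} model exons"
            )
        self.model = model
        self.alignments = list(alignments)
        self.maps: list[CoordinateMap] = []
        taxa0 = None
        for aln, spec in zip(self.alignments, model.exons):
            if aln.exon_id != spec.exon_id:
                raise ModelConsistencyError(
                    f"{model.gene_name}: alignment {aln.exon_id!r} does not "
                    f"match model exon {spec.exon_id!r}"
                )
            cmap = build_coordinate_map(aln)
            if cmap.ref_length != spec.length:
                raise ModelConsistencyError(
                    f"{model.gene_name}/{spec.exon_id}: reference span "
                    f"{cmap.ref_length} != model length {spec.length}"
                )
            self.maps.append(cmap)
            taxa = {r.taxon: r.role for r in aln.rows}
            if taxa0 is None:
                taxa0 = taxa
            elif taxa != taxa0:
                raise ModelConsistencyError(
                    f"{model.gene_name}: taxa/roles differ between exons"
                )
        self.roles: dict[str, str] = dict(taxa0)
        # flatten columns; index global reference positions
        self.columns: list[GlobalColumn] = []
        self.ref_columns: list[int] = []  # index into self.columns, per global ref pos
        for i, (aln, cmap) in enumerate(zip(self.alignments, self.maps)):
            for col, entry in enumerate(cmap.entries):
                self.columns.append(GlobalColumn(i, aln.exon_id, col, entry))
                if isinstance(entry, RefPosition):
                    self.ref_columns.append(len(self.columns) - 1)
        self._validate_native_stop()

    # -- residue access ----------------------------------------------------

    def residue(self, taxon: str, column: int) -> str:
        gc = self.columns[column]
        return self.alignments[gc.exon_idx].row(taxon).seq[gc.col]

    def reference_residues(self, column: int) -> frozenset[str]:
        """Non-gap reference residues at an alignment column (raw symbols)."""
        gc = self.columns[column]
        aln = self.alignments[gc.exon_idx]
        return frozenset(
            r.seq[gc.col] for r in aln.reference_rows if r.seq[gc.col] != GAP
        )

    def ref_position(self, g: int) -> RefPosition:
        """The (exon, position) of global reference index ``g`` (1-based)."""
        entry = self.columns[self.ref_columns[g - 1]].entry
        assert isinstance(entry, RefPosition)
        return entry

    @property
    def targets(self) -> list[str]:
        return [t for t, role in self.roles.items() if role == ROLE_TARGET]

    # -- CDS extraction ----------------------------------------------------

    def target_cds(self, taxon: str) -> list[tuple[str, int, Location]]:
        """Gap-stripped CDS of a taxon: (residue, global column, location)."""
        if taxon not in self.roles:
            raise KeyError(taxon)
        out = []
        for i, gc in enumerate(self.columns):
            base = self.alignments[gc.exon_idx].row(taxon).seq[gc.col]
            if base != GAP:
                out.append((base, i, gc.entry))
        return out

    def _validate_native_stop(self) -> None:
        ns = self.model.native_stop
        g0 = self.model.global_ref_index(ns.exon_id, ns.start)
        triplets = []
        cols = [self.columns[self.ref_columns[g - 1]] for g in range(g0, g0 + 3)]
        aln_rows = {}
        for gc in cols:
            aln = self.alignments[gc.exon_idx]
            for r in aln.reference_rows:
                aln_rows.setdefault(r.taxon, []).append(r.seq[gc.col])
        for taxon, bases in aln_rows.items():
            if GAP not in bases:
                triplets.append("".join(bases))
        if not any(t in STOP_CODONS for t in triplets):
            raise ModelConsistencyError(
                f"{self.model.gene_name}: no reference row carries a stop codon "
                f"at the annotated native stop ({ns.exon_id}:{ns.start})"
            )


def concatenate_gene(
    alignments: Sequence[ExonAlignment], model: GeneModel
) -> GeneView:
    """Concatenate exon alignments under the gene model's global frame."""
    return GeneView(alignments, model)
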