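"""Detection and classification of gene-inactivating mutations.

A lesion is called for a target taxon relative to the set of reference rows,
always in reference coordinates.  Four inactivating classes are recognised:

* ``nonsense_substitution`` — a substituted base turns the in-frame codon
  into TAA/TAG/TGA before the native stop, while no reference row's codon at
  that triplet is a stop.
* ``stop_insertion`` — an insertion whose inserted bases, read in the frame
  entering the insertion, contain a stop triplet lying entirely within the
  insertion.  Tallied with the nonsense class regardless of length mod 3.
* ``frameshift_insertion`` / ``frameshift_deletion`` — an indel with length
  not a multiple of 3.  The first premature stop downstream in the shifted
  frame (scanned across exon junctions, through all of the target's own
  inserted/deleted bases) is attached when one exists; inserted bases never
  consume reference positions, so the stop span is reported in reference
  coordinates of the exon that contains it.

Frame-preserving indels without an inserted stop are recorded as
``inframe_indel`` and flagged non-inactivating.

Zygosity is read from sequence ambiguity as in Sanger practice: a plain base
is a homozygous call; a 2-fold IUPAC code containing one reference and one
non-reference allele is heterozygous; 3- and 4-fold codes are uninformative
(no call).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment import (
    GAP,
    STOP_CODONS,
    ExonAlignment,
    GeneModel,
    GeneView,
    InsertionSlot,
    Location,
    RefInterval,
    RefPosition,
    concatenate_gene,
    expand,
    location_from_dict,
    location_to_dict,
)
from .errors import ClassificationError, TaxonError

NONSENSE_SUBSTITUTION = "nonsense_substitution"
STOP_INSERTION = "stop_insertion"
FRAMESHIFT_INSERTION = "frameshift_insertion"
FRAMESHIFT_DELETION = "frameshift_deletion"
INFRAME_INDEL = "inframe_indel"

INACTIVATING_CLASSES = frozenset(
    {NONSENSE_SUBSTITUTION, STOP_INSERTION, FRAMESHIFT_INSERTION, FRAMESHIFT_DELETION}
)
#: classes tallied together with nonsense mutations (premature stop created
#: directly), versus frameshifts (reading-frame shift).
NONSENSE_TYPE = frozenset({NONSENSE_SUBSTITUTION, STOP_INSERTION})
FRAMESHIFT_TYPE = frozenset({FRAMESHIFT_INSERTION, FRAMESHIFT_DELETION})

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class StopCodon:
    """A premature stop: triplet plus its reference-coordinate span."""

    triplet: str
    span: Optional[tuple[RefPosition, RefPosition]]
    exon_id: str

    def to_dict(self) -> dict:
        d: dict = {"triplet": self.triplet, "exon": self.exon_id}
        if self.span is not None:
            d["start"] = self.span[0].pos
            d["end"] = self.span[1].pos
            d["start_exon"] = self.span[0].exon_id
            d["end_exon"] = self.span[1].exon_id
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StopCodon":
        span = None
        if "start" in d:
            span = (
                RefPosition(d.get("start_exon", d["exon"]), int(d["start"])),
                RefPosition(d.get("end_exon", d["exon"]), int(d["end"])),
            )
        return cls(d["triplet"], span, d["exon"])


@dataclass
class MutationRecord:
    """One detected lesion in one target taxon."""

    taxon: str
    gene: str
    exon_id: str
    klass: str
    location: Location
    ref_alleles: frozenset[str]
    alt_allele: str
    indel_length: int
    zygosity: str
    premature_stop: Optional[StopCodon] = None

    def __post_init__(self) -> None:
        if self.klass in FRAMESHIFT_TYPE and self.indel_length % 3 == 0:
            raise ClassificationError(
                f"frameshift record with length {self.indel_length} % 3 == 0"
            )
        if self.klass == NONSENSE_SUBSTITUTION:
            ps = self.premature_stop
            if ps is None or ps.span is None:
                raise ClassificationError("nonsense record without a stop span")

    @property
    def inactivating(self) -> bool:
        return self.klass in INACTIVATING_CLASSES

    def to_dict(self) -> dict:
        d = {
            "taxon": self.taxon,
            "gene": self.gene,
            "exon": self.exon_id,
            "class": self.klass,
            "location": location_to_dict(self.location),
            "ref_alleles": sorted(self.ref_alleles),
            "alt": self.alt_allele,
            "indel_length": self.indel_length,
            "zygosity": self.zygosity,
        }
        if self.premature_stop is not None:
            d["premature_stop"] = self.premature_stop.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MutationRecord":
        ps = d.get("premature_stop")
        return cls(
            taxon=d["taxon"],
            gene=d["gene"],
            exon_id=d["exon"],
            klass=d["class"],
            location=location_from_dict(d["location"]),
            ref_alleles=frozenset(d["ref_alleles"]),
            alt_allele=d["alt"],
            indel_length=int(d["indel_length"]),
            zygosity=d["zygosity"],
            premature_stop=StopCodon.from_dict(ps) if ps else None,
        )


@dataclass
class LesionReport:
    """All lesions of one gene in one taxon, sorted 5'→3' along the gene."""

    taxon: str
    gene: str
    records: list[MutationRecord] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {"nonsense": 0, "frameshift": 0, "inframe": 0}
        for r in self.records:
            if r.klass in NONSENSE_TYPE:
                c["nonsense"] += 1
            elif r.klass in FRAMESHIFT_TYPE:
                c["frameshift"] += 1
            else:
                c["inframe"] += 1
        return c

    @property
    def inactivating_records(self) -> list[MutationRecord]:
        return [r for r in self.records if r.inactivating]

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "gene": self.gene,
            "records": [r.to_dict() for r in self.records],
            "counts": self.counts,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LesionReport":
        return cls(
            taxon=d["taxon"],
            gene=d["gene"],
            records=[MutationRecord.from_dict(x) for x in d["records"]],
        )


# ---------------------------------------------------------------------------
# zygosity
# ---------------------------------------------------------------------------

def call_zygosity(
    residue: str, ref_alleles: Iterable[str]
) -> Optional[tuple[str, tuple[str, ...]]]:
    """Call a variant at one site from a target residue and reference alleles.

    Returns ``(zygosity, mutant_alleles)`` or ``None`` when no mutation is
    called (target allele present among the references, or the residue is
    uninformative).
    """
    ref_expanded: set[str] = set()
    for a in ref_alleles:
        ref_expanded |= expand(a)
    t = expand(residue)
    if len(t) > 2:
        return None  # N/B/D/H/V: uninformative
    mutants = tuple(sorted(t - ref_expanded))
    if not mutants:
        return None
    if len(t) == 1:
        return (HOMOZYGOUS, mutants)
    # 2-fold code: heterozygous only if it also carries a reference allele
    if t & ref_expanded:
        return (HETEROZYGOUS, mutants)
    return None  # two distinct non-reference alleles: treat as uninformative


# ---------------------------------------------------------------------------
# nonsense substitutions
# ---------------------------------------------------------------------------

def detect_nonsense_substitutions(
    view: GeneView, target: str
) -> list[MutationRecord]:
    """Stop-creating substitutions in the reference reading frame.

    A record is emitted per codon where (i) at least one target residue
    differs from every reference allele, (ii) the codon built with the
    mutant allele(s) is a stop, (iii) no reference row's codon at the
    triplet is itself a stop, and (iv) the triplet precedes the native stop.
    """
    if target not in view.roles:
        raise TaxonError(f"taxon {target!r} not in alignment")
    model = view.model
    records: list[MutationRecord] = []
    for codon_idx in range(model.n_codons - 1):  # exclude the native stop
        gs = [codon_idx * 3 + k + 1 for k in range(3)]
        cols = [view.ref_columns[g - 1] for g in gs]
        bases = [view.residue(target, c) for c in cols]
        if GAP in bases:
            continue  # deletions handled elsewhere
        refsets = [view.reference_residues(c) for c in cols]
        calls = [call_zygosity(b, rs) for b, rs in zip(bases, refsets)]
        mutated = [k for k in range(3) if calls[k] is not None]
        if not mutated:
            continue
        eff = []
        ok = True
        for k in range(3):
            if calls[k] is not None:
                eff.append(calls[k][1][0])
            elif len(expand(bases[k])) == 1:
                eff.append(bases[k])
            else:
                ok = False  # uninformative residue: cannot confirm a stop
                break
        if not ok:
            continue
        codon = "".join(eff)
        if codon not in STOP_CODONS:
            continue
        if _any_reference_stop(view, cols):
            continue
        k0 = mutated[0]
        zyg = (
            HETEROZYGOUS
            if any(calls[k][0] == HETEROZYGOUS for k in mutated)
            else HOMOZYGOUS
        )
        loc = view.ref_position(gs[k0])
        span = (view.ref_position(gs[0]), view.ref_position(gs[2]))
        records.append(
            MutationRecord(
                taxon=target,
                gene=model.gene_name,
                exon_id=loc.exon_id,
                klass=NONSENSE_SUBSTITUTION,
                location=loc,
                ref_alleles=refsets[k0],
                alt_allele=calls[k0][1][0],
                indel_length=0,
                zygosity=zyg,
                premature_stop=StopCodon(codon, span, span[0].exon_id),
            )
        )
    return records


def _any_reference_stop(view: GeneView, cols: Sequence[int]) -> bool:
    """True if any single reference row spells a plain stop over the columns."""
    per_row: dict[str, list[str]] = {}
    for c in cols:
        gc = view.columns[c]
        aln = view.alignments[gc.exon_idx]
        for r in aln.reference_rows:
            per_row.setdefault(r.taxon, []).append(r.seq[gc.col])
    for bases in per_row.values():
        if len(bases) == 3 and GAP not in bases and "".join(bases) in STOP_CODONS:
            return True
    return False


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------

def detect_indels(view: GeneView, target: str) -> list[MutationRecord]:
    """Maximal runs of target-only insertions and deletions, one record each.

    Runs are broken by any matched column and at exon junctions, so two
    indels separated by at least one matched column are distinct records.
    """
    if target not in view.roles:
        raise TaxonError(f"taxon {target!r} not in alignment")
    model = view.model
    records: list[MutationRecord] = []
    ref_seen = 0  # global reference positions consumed so far

    ins_anchor: Optional[int] = None  # global ref index of slot anchor
    ins_exon: Optional[str] = None
    ins_local_after: Optional[int] = None
    ins_bases: list[str] = []
    del_start: Optional[RefPosition] = None
    del_end: Optional[RefPosition] = None
    cur_exon_idx = -1

    def flush_insertion() -> None:
        nonlocal ins_anchor, ins_exon, ins_local_after, ins_bases
        if ins_anchor is None:
            return
        records.append(
            _classify_insertion(
                view, target, ins_exon, ins_local_after, ins_anchor, "".join(ins_bases)
            )
        )
        ins_anchor = None
        ins_exon = None
        ins_local_after = None
        ins_bases = []

    def flush_deletion() -> None:
        nonlocal del_start, del_end
        if del_start is None:
            return
        length = del_end.pos - del_start.pos + 1
        klass = FRAMESHIFT_DELETION if length % 3 else INFRAME_INDEL
        records.append(
            MutationRecord(
                taxon=target,
                gene=model.gene_name,
                exon_id=del_start.exon_id,
                klass=klass,
                location=RefInterval(del_start.exon_id, del_start.pos, del_end.pos),
                ref_alleles=frozenset(),
                alt_allele="",
                indel_length=length,
                zygosity=HOMOZYGOUS,
            )
        )
        del_start = None
        del_end = None

    for gc in view.columns:
        if gc.exon_idx != cur_exon_idx:
            flush_insertion()
            flush_deletion()
            cur_exon_idx = gc.exon_idx
        base = view.alignments[gc.exon_idx].row(target).seq[gc.col]
        if isinstance(gc.entry, RefPosition):
            ref_seen += 1
            flush_insertion()
            if base == GAP:
                if del_start is None:
                    del_start = gc.entry
                del_end = gc.entry
            else:
                flush_deletion()
        else:  # insertion slot
            flush_deletion()
            if base == GAP:
                flush_insertion()
            else:
                if ins_anchor is None:
                    ins_anchor = ref_seen
                    ins_exon = gc.entry.exon_id
                    ins_local_after = gc.entry.after
                ins_bases.append(base)
    flush_insertion()
    flush_deletion()
    return records


def _classify_insertion(
    view: GeneView,
    target: str,
    exon_id: str,
    local_after: int,
    global_anchor: int,
    inserted: str,
) -> MutationRecord:
    model = view.model
    carried = global_anchor % 3
    carried_bases = []
    for g in range(global_anchor - carried + 1, global_anchor + 1):
        if g >= 1:
            b = view.residue(target, view.ref_columns[g - 1])
            if b != GAP:
                carried_bases.append(b)
    reading = "".join(carried_bases) + inserted
    n_carried = len(carried_bases)
    stop: Optional[str] = None
    for k in range(len(reading) // 3):
        cod = reading[3 * k : 3 * k + 3]
        if 3 * k >= n_carried and cod in STOP_CODONS:
            stop = cod  # stop lies entirely within the inserted bases
            break
    length = len(inserted)
    if stop is not None:
        klass = STOP_INSERTION
        premature = StopCodon(stop, None, exon_id)
    elif length % 3:
        klass = FRAMESHIFT_INSERTION
        premature = None
    else:
        klass = INFRAME_INDEL
        premature = None
    return MutationRecord(
        taxon=target,
        gene=model.gene_name,
        exon_id=exon_id,
        klass=klass,
        location=InsertionSlot(exon_id, local_after),
        ref_alleles=frozenset(),
        alt_allele=inserted,
        indel_length=length,
        zygosity=HOMOZYGOUS,
        premature_stop=premature,
    )


# ---------------------------------------------------------------------------
# downstream premature stop for frameshifts
# ---------------------------------------------------------------------------

def locate_downstream_premature_stop(
    view: GeneView, target: str, fs: MutationRecord
) -> Optional[StopCodon]:
    """First stop triplet downstream of a frameshift in the shifted frame.

    The target's own gap-stripped CDS is translated from the codon containing
    the frameshift onward (its frame therefore reflects every upstream indel
    of the target), continuing across exon junctions and through any
    subsequently inserted or deleted target bases, until the first stop or
    the CDS end.  The stop span is mapped back through the coordinate map;
    inserted bases do not consume reference positions.  Returns ``None`` when
    no stop precedes the CDS end, or when the first stop found is the native
    terminal stop itself.
    """
    if fs.klass not in FRAMESHIFT_TYPE:
        raise ClassificationError(f"record class {fs.klass!r} is not a frameshift")
    if fs.taxon != target:
        raise ClassificationError("frameshift record belongs to another taxon")
    cds = view.target_cds(target)
    i0 = _frameshift_cds_index(view, cds, fs)
    if i0 is None:
        return None
    model = view.model
    ns = model.native_stop
    native = {
        (ns.exon_id, ns.start + k) for k in range(3)
    }
    start = (i0 // 3) * 3
    for c in range(start, len(cds) - 2, 3):
        triplet = "".join(cds[c + k][0] for k in range(3))
        if triplet not in STOP_CODONS:
            continue
        coords = [cds[c + k][2] for k in range(3)]
        spots = {
            (e.exon_id, e.pos) for e in coords if isinstance(e, RefPosition)
        }
        if spots == native:
            return None  # reached the annotated terminal stop in frame
        first = coords[0] if isinstance(coords[0], RefPosition) else None
        last = coords[2] if isinstance(coords[2], RefPosition) else None
        span = (first, last) if (first and last) else None
        exon = (first or last or coords[0]).exon_id
        return StopCodon(triplet, span, exon)
    return None


def _frameshift_cds_index(
    view: GeneView, cds: list[tuple[str, int, Location]], fs: MutationRecord
) -> Optional[int]:
    if fs.klass == FRAMESHIFT_INSERTION:
        loc = fs.location
        for i, (_, _, entry) in enumerate(cds):
            if (
                isinstance(entry, InsertionSlot)
                and entry.exon_id == loc.exon_id
                and entry.after == loc.after
            ):
                return i
        return None
    # deletion: first CDS base past the deleted reference interval
    loc = fs.location
    g_end = view.model.global_ref_index(loc.exon_id, loc.end)
    for i, (_, _, entry) in enumerate(cds):
        if isinstance(entry, RefPosition):
            g = view.model.global_ref_index(entry.exon_id, entry.pos)
            if g > g_end:
                return i
    return None


# ---------------------------------------------------------------------------
# whole-gene scan
# ---------------------------------------------------------------------------

def scan_gene(
    alignments: Sequence[ExonAlignment] | GeneView,
    model: Optional[GeneModel] = None,
    target: str = "",
) -> LesionReport:
    """Run all detectors for one target taxon and assemble a sorted report."""
    if isinstance(alignments, GeneView):
        view = alignments
    else:
        view = concatenate_gene(alignments, model)
    if target not in view.roles:
        raise TaxonError(f"taxon {target!r} not in alignment")
    records = detect_nonsense_substitutions(view, target)
    records += detect_indels(view, target)
    for i, rec in enumerate(records):
        if rec.klass in FRAMESHIFT_TYPE:
            ps = locate_downstream_premature_stop(view, target, rec)
            if ps is not None:
                records[i] = dataclasses.replace(rec, premature_stop=ps)
    records.sort(
        key=lambda r: (view.model.exon_index(r.exon_id), r.location.sort_pos())
    )
    return LesionReport(taxon=target, gene=view.model.gene_name, records=records)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "taxon", "gene", "exon", "class", "location", "ref_alleles", "alt",
    "indel_length", "zygosity", "stop_triplet", "stop_span",
]


def records_to_tsv_rows(reports: Iterable[LesionReport]) -> list[list[str]]:
    rows = []
    for rep in reports:
        for r in rep.records:
            if r.premature_stop is not None:
                trip = r.premature_stop.triplet
                span = (
                    f"{r.premature_stop.span[0].pos}-{r.premature_stop.span[1].pos}"
                    if r.premature_stop.span
                    else "."
                )
            else:
                trip, span = ".", "."
            rows.append([
                r.taxon, r.gene, r.exon_id, r.klass, r.location.key(),
                ",".join(sorted(r.ref_alleles)) or ".", r.alt_allele or ".",
                str(r.indel_length), r.zygosity, trip, span,
            ])
    return rows


def write_records_tsv(reports: Iterable[LesionReport], path) -> None:
    rows = records_to_tsv_rows(reports)
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
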