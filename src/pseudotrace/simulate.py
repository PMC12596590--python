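"""Synthetic coding-sequence evolution with a planted gene-loss event.

The generator emulates the data situation of a pseudogene survey: a set of
functional reference species and target species whose gene may have decayed.
A functional reference CDS (uniform-random sense codons plus a terminal
stop) evolves along a dated tree under a Jukes–Cantor-style substitution
process (rate ``mu`` substitutions/site/My, equal exchange among the three
alternative bases).  Lineages outside the planted loss branch are under
purifying constraint, implemented as rejection sampling: any proposed change
that would create an internal stop codon (or destroy the terminal stop) is
rejected, and indels are forbidden (optionally, rare frame-preserving
insertions can be enabled).  On the loss branch and all its descendants the
constraint is lifted: every substitution is accepted and indels occur at
rate ``indel_rate`` events/site/My with geometrically distributed lengths.

The output is a true multiple alignment (inserted columns are shared by the
descendants that inherit them) plus a :class:`SimTruth` log of every applied
event, which recovery tests compare against.  ``plant_fixture_mutations``
builds deterministic fixtures instead: a catalogue of explicitly described
lesions applied to designated target taxa over an otherwise identical
reference alignment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .alignment import (
    GAP,
    STOP_CODONS,
    AlignedRow,
    ExonAlignment,
    ExonSpec,
    GeneModel,
    ROLE_REFERENCE,
    ROLE_TARGET,
)
from .errors import ConfigError, LesionSpecError
from .phylo import TimeTree

BASES = ("A", "C", "G", "T")
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one simulation.

    ``exon_lengths`` must sum to ``3 * n_codons + 3`` (the extra codon is
    the native terminal stop).  ``loss_branch`` is a ``(parent_label,
    child_label)`` pair naming the branch on which function is lost, or
    ``None`` for a fully functional clade.  A fixed seed makes the output
    byte-identical between runs.
    """

    n_codons: int
    mu: float = 0.005                     # substitutions/site/My
    indel_rate: float = 0.002             # post-loss indel events/site/My
    indel_mean_length: float = 2.0        # geometric mean, bp
    exon_lengths: Optional[list[int]] = None
    loss_branch: Optional[tuple[str, str]] = None
    functional_inframe_insertion_rate: float = 0.0
    gene_name: str = "simgene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 2:
            raise ConfigError("n_codons must be at least 2")
        if min(self.mu, self.indel_rate) < 0:
            raise ConfigError("rates must be non-negative")
        if self.indel_mean_length < 1:
            raise ConfigError("indel_mean_length must be >= 1")
        total = 3 * self.n_codons + 3
        if self.exon_lengths is None:
            self.exon_lengths = [total]
        if any(x <= 0 for x in self.exon_lengths):
            raise ConfigError("exon lengths must be positive")
        if sum(self.exon_lengths) != total:
            raise ConfigError(
                f"exon lengths sum to {sum(self.exon_lengths)}, "
                f"expected 3*n_codons+3 = {total}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loss_branch"] = list(self.loss_branch) if self.loss_branch else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        lb = d.get("loss_branch")
        if lb is not None:
            d["loss_branch"] = (lb[0], lb[1])
        return cls(**d)


# ---------------------------------------------------------------------------
# functional reference CDS
# ---------------------------------------------------------------------------

def generate_functional_cds(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[str, GeneModel]:
    """Uniform-random sense codons plus a terminal stop, cut into exons."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    codons = rng.choice(len(SENSE_CODONS), size=config.n_codons)
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    cds = "".join(SENSE_CODONS[i] for i in codons) + stop
    exons = []
    phase = 0
    for i, length in enumerate(config.exon_lengths):
        exons.append(ExonSpec(f"exon{i + 1}", length, phase))
        phase = (phase + length) % 3
    model = GeneModel(config.gene_name, exons)
    return cds, model


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

#: column key of an ancestral (reference) base: ((exon_idx, pos),)
#: inserted bases extend the anchor's key with (event_id, offset) pairs, so
#: lexicographic order of keys is a consistent global column order.
ColumnKey = tuple[tuple[int, int], ...]

_BEFORE_ALL: ColumnKey = ((-1, -1),)


@dataclass
class SimTruth:
    """Ground truth of a simulation: the planted branch and every applied
    event, per branch, in application order.

    The ``inactivating`` flag on events is an upper bound on what the
    detector can see (substitutions are flagged when the new base completes
    a stop triplet in any frame), so the number of inactivating records
    detected on a tip never exceeds the flagged events on its root path.
    """

    loss_branch: Optional[tuple[str, str]]
    seed: int
    events: dict[str, list[dict]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def path_events(self, tree: TimeTree, tip: str) -> list[dict]:
        out = []
        label = tip
        chain = []
        while label is not None:
            parent = tree.parent_label(label)
            if parent is not None:
                chain.append(f"{parent}->{label}")
            label = parent
        for key in reversed(chain):
            out.extend(self.events.get(key, []))
        return out

    def to_dict(self) -> dict:
        return {
            "loss_branch": list(self.loss_branch) if self.loss_branch else None,
            "seed": self.seed,
            "events": self.events,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimResult:
    model: GeneModel
    config: SimConfig
    tip_order: list[str]
    rows: dict[str, dict[str, str]]  # exon_id -> taxon -> aligned row
    truth: SimTruth

    def default_roles(self, tree: TimeTree) -> dict[str, str]:
        if self.config.loss_branch is None:
            raise ConfigError(
                "no loss branch: pass roles explicitly to exon_alignments()"
            )
        below = tree.tips_below(self.config.loss_branch[1])
        return {
            t: (ROLE_TARGET if t in below else ROLE_REFERENCE)
            for t in self.tip_order
        }

    def exon_alignments(
        self, roles: Optional[Mapping[str, str]] = None,
        tree: Optional[TimeTree] = None,
    ) -> list[ExonAlignment]:
        if roles is None:
            if tree is None:
                raise ConfigError("need roles or a tree to derive them")
            roles = self.default_roles(tree)
        out = []
        for spec in self.model.exons:
            taxon_rows = self.rows[spec.exon_id]
            out.append(
                ExonAlignment(
                    spec.exon_id,
                    [
                        AlignedRow(t, roles[t], taxon_rows[t])
                        for t in self.tip_order
                    ],
                )
            )
        return out


class _Evolver:
    def __init__(self, config: SimConfig, model: GeneModel,
                 rng: np.random.Generator):
        self.config = config
        self.model = model
        self.rng = rng
        self.event_counter = 0

    def _stop_in_any_frame(self, seq: list[str], i: int) -> bool:
        lo = max(0, i - 2)
        window = "".join(seq[lo : i + 3])
        return any(
            window[k : k + 3] in STOP_CODONS for k in range(len(window) - 2)
        )

    def substitute(self, keys, seq, t: float, functional: bool, log: list) -> None:
        rng = self.rng
        L = len(seq)
        n = rng.poisson(self.config.mu * t * L)
        for _ in range(n):
            i = int(rng.integers(L))
            old = seq[i]
            alts = [b for b in BASES if b != old]
            new = alts[int(rng.integers(3))]
            if functional:
                c = i // 3
                codon = seq[3 * c : 3 * c + 3]
                codon[i - 3 * c] = new
                triplet = "".join(codon)
                last = L // 3 - 1
                if c < last and triplet in STOP_CODONS:
                    continue  # purifying: reject internal stop
                if c == last and triplet not in STOP_CODONS:
                    continue  # purifying: keep the terminal stop
            seq[i] = new
            log.append({
                "type": "substitution",
                "column": _key_str(keys[i]),
                "from": old,
                "to": new,
                "inactivating": (not functional)
                and self._stop_in_any_frame(seq, i),
            })

    def indels(self, keys, seq, t: float, log: list) -> None:
        rng = self.rng
        cfg = self.config
        n = rng.poisson(cfg.indel_rate * t * len(seq))
        p = 1.0 / cfg.indel_mean_length
        for _ in range(n):
            length = int(rng.geometric(p))
            if rng.random() < 0.5 and len(seq) > length:
                # deletion
                start = int(rng.integers(len(seq) - length + 1))
                removed = "".join(seq[start : start + length])
                log.append({
                    "type": "deletion",
                    "start_column": _key_str(keys[start]),
                    "length": length,
                    "removed": removed,
                    "inactivating": length % 3 != 0,
                })
                del seq[start : start + length]
                del keys[start : start + length]
            else:
                pos = int(rng.integers(len(seq) + 1))
                bases = [BASES[int(b)] for b in rng.integers(4, size=length)]
                self.event_counter += 1
                eid = self.event_counter
                anchor = keys[pos - 1] if pos > 0 else _BEFORE_ALL
                new_keys = [anchor + ((eid, j),) for j in range(1, length + 1)]
                ins = "".join(bases)
                # any-frame check keeps the flag an upper bound on detection
                has_stop = any(
                    ins[k : k + 3] in STOP_CODONS for k in range(length - 2)
                )
                log.append({
                    "type": "insertion",
                    "anchor_column": _key_str(anchor),
                    "length": length,
                    "seq": ins,
                    "inactivating": length % 3 != 0 or has_stop,
                })
                seq[pos:pos] = bases
                keys[pos:pos] = new_keys

    def inframe_insertions(self, keys, seq, t: float, log: list) -> None:
        """Optional frame-preserving insertions on functional lineages."""
        rng = self.rng
        rate = self.config.functional_inframe_insertion_rate
        if rate <= 0:
            return
        n = rng.poisson(rate * t * len(seq))
        for _ in range(n):
            n_cod = int(rng.geometric(0.5))
            codons = [SENSE_CODONS[int(i)]
                      for i in rng.integers(len(SENSE_CODONS), size=n_cod)]
            c = int(rng.integers(len(seq) // 3))  # codon boundary
            pos = 3 * c
            bases = list("".join(codons))
            self.event_counter += 1
            eid = self.event_counter
            anchor = keys[pos - 1] if pos > 0 else _BEFORE_ALL
            new_keys = [anchor + ((eid, j),) for j in range(1, len(bases) + 1)]
            log.append({
                "type": "insertion",
                "anchor_column": _key_str(anchor),
                "length": len(bases),
                "seq": "".join(bases),
                "inactivating": False,
            })
            seq[pos:pos] = bases
            keys[pos:pos] = new_keys


def _key_str(key: ColumnKey) -> str:
    return "/".join(f"{a}.{b}" for a, b in key)


def simulate_clade(
    cds: str,
    model: GeneModel,
    tree: TimeTree,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimResult:
    """Evolve the reference CDS along the tree; returns alignments + truth.

    Branches are visited in preorder with a single seeded generator, so a
    fixed (config, seed) pair reproduces the output exactly.
    """
    if config.loss_branch is not None:
        parent, child = config.loss_branch
        if child not in tree or tree.parent_label(child) != parent:
            raise ConfigError(
                f"loss branch {config.loss_branch} not found in tree"
            )
    if len(cds) != model.total_length:
        raise ConfigError("CDS length does not match the gene model")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ev = _Evolver(config, model, rng)
    truth = SimTruth(
        loss_branch=config.loss_branch, seed=config.seed,
        config=config.to_dict(),
    )
    # root state: reference columns keyed by (exon_idx, 1-based pos)
    keys: list[ColumnKey] = []
    for i, spec in enumerate(model.exons):
        keys.extend(((i, p),) for p in range(1, spec.length + 1))
    root_state = (keys, list(cds))

    tip_states: dict[str, tuple[list[ColumnKey], list[str]]] = {}

    def walk(label: str, state, functional: bool) -> None:
        for child in tree.children_labels(label):
            child_keys = list(state[0])
            child_seq = list(state[1])
            t = tree.age(label) - tree.age(child)
            child_functional = functional and (
                config.loss_branch is None
                or (label, child) != tuple(config.loss_branch)
            )
            log: list[dict] = []
            ev.substitute(child_keys, child_seq, t, child_functional, log)
            if child_functional:
                ev.inframe_insertions(child_keys, child_seq, t, log)
            else:
                ev.indels(child_keys, child_seq, t, log)
            truth.events[f"{label}->{child}"] = log
            child_state = (child_keys, child_seq)
            if tree.is_tip(child):
                tip_states[child] = child_state
            else:
                walk(child, child_state, child_functional)

    root = tree.root_label
    if tree.is_tip(root):
        tip_states[root] = root_state
    else:
        walk(root, root_state, True)

    # assemble the alignment from the union of surviving columns
    all_keys = sorted(set().union(*(set(k) for k, _ in tip_states.values())))
    tip_order = list(tree.tip_labels)
    lookup = {
        tip: dict(zip(k, s)) for tip, (k, s) in tip_states.items()
    }
    rows: dict[str, dict[str, str]] = {
        spec.exon_id: {} for spec in model.exons
    }
    per_exon_keys: dict[int, list[ColumnKey]] = {}
    for key in all_keys:
        exon_idx = key[0][0] if key[0] != (-1, -1) else 0
        per_exon_keys.setdefault(exon_idx, []).append(key)
    for i, spec in enumerate(model.exons):
        exon_keys = per_exon_keys.get(i, [])
        for tip in tip_order:
            look = lookup[tip]
            rows[spec.exon_id][tip] = "".join(
                look.get(k, GAP) for k in exon_keys
            )
    return SimResult(model=model, config=config, tip_order=tip_order,
                     rows=rows, truth=truth)


# ---------------------------------------------------------------------------
# deterministic fixture construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """Descriptor of one planted lesion.

    kinds: ``substitution`` (position, ``seq`` = the new residue),
    ``insertion`` (``position`` = the reference position the insertion
    follows, ``seq`` = inserted bases), ``deletion`` (``position`` = first
    deleted reference position, ``length`` = bp removed).  ``taxa`` are the
    carriers; carriers of one descriptor share alignment columns, so the
    same descriptor applied to two taxa is one identical (shared) lesion.
    """

    kind: str
    exon_id: str
    position: int
    taxa: tuple[str, ...]
    seq: str = ""
    length: int = 0


def plant_fixture_mutations(
    cds: str,
    model: GeneModel,
    lesions: Sequence[LesionSpec],
    reference_taxa: Sequence[str],
    target_taxa: Sequence[str] = (),
    reference_overrides: Optional[Mapping[tuple[str, int], Mapping[str, str]]] = None,
) -> list[ExonAlignment]:
    """Build exon alignments with the given lesions applied to their carriers.

    All taxa start from the reference CDS.  ``reference_overrides`` plants
    reference-site polymorphism: ``{(exon_id, pos): {taxon: base}}``.
    """
    if len(cds) != model.total_length:
        raise LesionSpecError("CDS length does not match the gene model")
    overrides = reference_overrides or {}
    targets = list(dict.fromkeys(
        list(target_taxa) + [t for l in lesions for t in l.taxa]
    ))
    # slice the reference per exon
    exon_seq: dict[str, str] = {}
    off = 0
    for spec in model.exons:
        exon_seq[spec.exon_id] = cds[off : off + spec.length]
        off += spec.length
    # validate descriptors
    for l in lesions:
        spec = model.exon(l.exon_id)
        if l.kind == "substitution":
            if not (1 <= l.position <= spec.length) or len(l.seq) != 1:
                raise LesionSpecError(f"substitution out of bounds: {l}")
        elif l.kind == "insertion":
            if not (1 <= l.position <= spec.length) or not l.seq:
                raise LesionSpecError(f"insertion out of bounds: {l}")
        elif l.kind == "deletion":
            if l.length < 1 or not (
                1 <= l.position and l.position + l.length - 1 <= spec.length
            ):
                raise LesionSpecError(f"deletion out of bounds: {l}")
        else:
            raise LesionSpecError(f"unknown lesion kind {l.kind!r}")
        if set(l.seq) - set(BASES):
            raise LesionSpecError(f"lesion sequence must be plain bases: {l}")

    alignments = []
    for spec in model.exons:
        ref = exon_seq[spec.exon_id]
        L = spec.length
        # start every row as the reference, as single-base cells
        cells: dict[str, list[str]] = {}
        for taxon in list(reference_taxa) + targets:
            cells[taxon] = list(ref)
        for (exon_id, pos), per_taxon in overrides.items():
            if exon_id != spec.exon_id:
                continue
            for taxon, base in per_taxon.items():
                cells[taxon][pos - 1] = base
        for l in lesions:
            if l.exon_id != spec.exon_id:
                continue
            for taxon in l.taxa:
                if l.kind == "substitution":
                    cells[taxon][l.position - 1] = l.seq
                elif l.kind == "deletion":
                    for p in range(l.position - 1, l.position - 1 + l.length):
                        cells[taxon][p] = GAP
        # insertion columns: blocks after each anchor, in descriptor order
        ins_here = [l for l in lesions
                    if l.kind == "insertion" and l.exon_id == spec.exon_id]
        blocks: dict[int, list[LesionSpec]] = {}
        for l in ins_here:
            blocks.setdefault(l.position, []).append(l)
        all_taxa = list(reference_taxa) + targets
        out_cols: dict[str, list[str]] = {t: [] for t in all_taxa}
        for p in range(0, L + 1):
            if p > 0:
                for t in all_taxa:
                    out_cols[t].append(cells[t][p - 1])
            for l in blocks.get(p, []):
                for t in all_taxa:
                    piece = l.seq if t in l.taxa else GAP * len(l.seq)
                    out_cols[t].extend(piece)
        rows = [
            AlignedRow(t, ROLE_REFERENCE, "".join(out_cols[t]))
            for t in reference_taxa
        ] + [
            AlignedRow(t, ROLE_TARGET, "".join(out_cols[t]))
            for t in targets
        ]
        alignments.append(ExonAlignment(spec.exon_id, rows))
    return alignments
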