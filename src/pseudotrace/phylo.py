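"""Dollo mapping of shared lesions onto a time-calibrated phylogeny.

Identical lesions across taxa (same gene, exon, location, class, allele and
length) are merged into a :class:`LesionGroup`.  Under Dollo parsimony an
inactivating lesion, once fixed, is never reverted, so each group is
assigned the minimal number of origin branches: one per maximal clade whose
sampled tips are all carriers.  A group whose carriers are not a sampled
clade receives multiple origins and is flagged as homoplasy.

Gene loss is then bracketed in time: the loss branch is the assigned branch
closest to the root whose sampled descendants are all pseudogenes for the
gene, and the loss interval is [age(child), age(parent)] in Mya.  Tips
without lesion reports (unsampled species) are carried along explicitly so
that predictions about them are always marked as predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .errors import LabelError, TreeError
from .lesions import LesionReport, MutationRecord
from .status import PSEUDOGENE, UNKNOWN, GeneStatus

#: relative root-to-tip deviation accepted when checking ultrametricity
ULTRAMETRIC_TOL = 1e-6


# ---------------------------------------------------------------------------
# time tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Branch:
    """An edge of the rooted tree, identified by its endpoint labels.

    ``parent`` is ``None`` for the root's own (stem) edge, which can carry an
    origin when every sampled tip is a carrier; its age interval is then
    clamped to the root age.
    """

    parent: Optional[str]
    child: str


class TimeTree:
    """A rooted ultrametric tree with node ages in Mya."""

    def __init__(self, tree: dendropy.Tree, tolerance: float = ULTRAMETRIC_TOL):
        self._tree = tree
        root = tree.seed_node
        # depths from root
        depth: dict[int, float] = {id(root): 0.0}
        order = []
        for node in tree.preorder_node_iter():
            order.append(node)
            if node is root:
                continue
            length = node.edge.length
            if length is None:
                raise TreeError("branch without a length")
            if length < 0:
                raise TreeError("negative branch length")
            depth[id(node)] = depth[id(node.parent_node)] + length
        tips = [n for n in order if n.is_leaf()]
        if not tips:
            raise TreeError("tree has no tips")
        height = max(depth[id(t)] for t in tips)
        if height > 0:
            worst = max(abs(depth[id(t)] - height) for t in tips)
            if worst > tolerance * height:
                raise TreeError(
                    f"tree not ultrametric: tip depth deviation {worst:g} "
                    f"exceeds tolerance {tolerance:g} x height {height:g}"
                )
        self._age: dict[str, float] = {}
        self._label: dict[int, str] = {}
        self._node: dict[str, dendropy.Node] = {}
        counter = 0
        for node in order:
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if not label:
                    raise TreeError("tip without a label")
            else:
                label = node.label
                if not label:
                    counter += 1
                    label = f"N{counter}"
            if label in self._node:
                raise TreeError(f"duplicate label {label!r}")
            self._label[id(node)] = label
            self._node[label] = node
            age = height - depth[id(node)]
            self._age[label] = 0.0 if abs(age) < tolerance * max(height, 1.0) else age
        self.root_label = self._label[id(root)]
        self.tip_labels = [self._label[id(t)] for t in tips]

    # -- queries -----------------------------------------------------------

    def __contains__(self, label: str) -> bool:
        return label in self._node

    def age(self, label: str) -> float:
        return self._age[label]

    @property
    def root_age(self) -> float:
        return self._age[self.root_label]

    def parent_label(self, label: str) -> Optional[str]:
        node = self._node[label]
        if node.parent_node is None:
            return None
        return self._label[id(node.parent_node)]

    def children_labels(self, label: str) -> list[str]:
        return [self._label[id(c)] for c in self._node[label].child_nodes()]

    def is_tip(self, label: str) -> bool:
        return self._node[label].is_leaf()

    def tips_below(self, label: str) -> frozenset[str]:
        node = self._node[label]
        if node.is_leaf():
            return frozenset({label})
        return frozenset(
            self._label[id(t)] for t in node.leaf_iter()
        )

    def postorder_labels(self) -> list[str]:
        return [self._label[id(n)] for n in self._tree.postorder_node_iter()]

    def is_descendant(self, label: str, ancestor: str) -> bool:
        """True if ``label`` lies in the subtree rooted at ``ancestor``
        (a node is its own descendant)."""
        node = self._node[label]
        anc = self._node[ancestor]
        while node is not None:
            if node is anc:
                return True
            node = node.parent_node
        return False

    def branch_of(self, child: str) -> Branch:
        return Branch(self.parent_label(child), child)

    def branch_interval(self, branch: Branch) -> tuple[float, float]:
        lo = self.age(branch.child)
        hi = self.age(branch.parent) if branch.parent is not None else self.root_age
        return (lo, hi)


def parse_time_tree(source: str | Path, tolerance: float = ULTRAMETRIC_TOL) -> TimeTree:
    """Parse a Newick time tree (text or file path); lengths are in My."""
    text = str(source)
    if "(" not in text and ";" not in text:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise TreeError(f"cannot parse Newick: {exc}") from exc
    return TimeTree(tree, tolerance=tolerance)


# ---------------------------------------------------------------------------
# lesion groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GroupKey:
    gene: str
    exon_id: str
    location: str
    klass: str
    alt: str
    indel_length: int


@dataclass
class LesionGroup:
    key: GroupKey
    carriers: frozenset[str]
    records: list[MutationRecord] = field(default_factory=list)

    @property
    def inactivating(self) -> bool:
        return any(r.inactivating for r in self.records)

    def to_dict(self) -> dict:
        return {
            "gene": self.key.gene,
            "exon": self.key.exon_id,
            "location": self.key.location,
            "class": self.key.klass,
            "alt": self.key.alt,
            "indel_length": self.key.indel_length,
            "carriers": sorted(self.carriers),
        }


def group_shared_lesions(reports: Iterable[LesionReport]) -> list[LesionGroup]:
    """Merge identical lesions across taxa; invariant to report order."""
    groups: dict[GroupKey, LesionGroup] = {}
    for rep in reports:
        for rec in rep.records:
            key = GroupKey(
                gene=rec.gene,
                exon_id=rec.exon_id,
                location=rec.location.key(),
                klass=rec.klass,
                alt=rec.alt_allele,
                indel_length=rec.indel_length,
            )
            if key not in groups:
                groups[key] = LesionGroup(key, frozenset())
            g = groups[key]
            g.carriers = g.carriers | {rec.taxon}
            g.records.append(rec)
    return sorted(groups.values(), key=lambda g: g.key)


# ---------------------------------------------------------------------------
# Dollo origin assignment
# ---------------------------------------------------------------------------

@dataclass
class OriginAssignment:
    group: LesionGroup
    branches: list[Branch]
    homoplasy: bool

    @property
    def n_origins(self) -> int:
        return len(self.branches)


def assign_origin_branches(
    groups: Sequence[LesionGroup],
    tree: TimeTree,
    sampled: Iterable[str],
) -> list[OriginAssignment]:
    """Dollo single-origin rule per group.

    ``sampled`` is the set of tips with lesion reports (carriers or known
    clean); unsampled tips neither support nor veto an origin.  Each group's
    origins are the stem branches of the maximal clades whose sampled tips
    are all carriers; more than one origin flags homoplasy.
    """
    sampled_set = set(sampled)
    tips = set(tree.tip_labels)
    missing = sampled_set - tips
    if missing:
        raise LabelError(f"sampled taxa not in tree: {sorted(missing)}")
    out = []
    for group in groups:
        bad = group.carriers - tips
        if bad:
            raise LabelError(f"carriers not in tree: {sorted(bad)}")
        carriers = set(group.carriers)
        eff_sampled = sampled_set | carriers
        n_samp: dict[str, int] = {}
        n_carr: dict[str, int] = {}
        for label in tree.postorder_labels():
            if tree.is_tip(label):
                n_samp[label] = 1 if label in eff_sampled else 0
                n_carr[label] = 1 if label in carriers else 0
            else:
                kids = tree.children_labels(label)
                n_samp[label] = sum(n_samp[k] for k in kids)
                n_carr[label] = sum(n_carr[k] for k in kids)
        def carried(label: str) -> bool:
            return n_samp[label] > 0 and n_samp[label] == n_carr[label]
        branches = []
        for label in tree.postorder_labels():
            if carried(label):
                parent = tree.parent_label(label)
                if parent is None or not carried(parent):
                    branches.append(Branch(parent, label))
        branches.sort(key=lambda b: (-tree.age(b.child), b.child))
        out.append(OriginAssignment(group, branches, homoplasy=len(branches) > 1))
    return out


# ---------------------------------------------------------------------------
# gene-loss dating
# ---------------------------------------------------------------------------

@dataclass
class LossEvent:
    gene: str
    branch: Branch
    interval_mya: tuple[float, float]
    causal_groups: list[LesionGroup]
    predicted_tips: list[str]

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "branch": [self.branch.parent, self.branch.child],
            "interval_mya": [self.interval_mya[0], self.interval_mya[1]],
            "causal_groups": [g.to_dict() for g in self.causal_groups],
            "predicted_tips": list(self.predicted_tips),
        }


def date_gene_loss(
    assignments: Sequence[OriginAssignment],
    statuses: Mapping[str, GeneStatus | str],
    tree: TimeTree,
    gene: Optional[str] = None,
) -> list[LossEvent]:
    """Bracket gene loss on the tree from assigned inactivating groups.

    ``statuses`` maps tip label to a :class:`GeneStatus` (or a plain status
    string) for the gene in question; tips absent from the mapping, or
    mapped to ``unknown``, are treated as unsampled.  Candidate branches are
    the assigned origins whose sampled descendants are all pseudogenes; a
    candidate nested under another candidate is absorbed by the more
    rootward one, so independent origins (homoplasy) yield one event each.
    Returns an empty list when no inactivating group exists.
    """
    def status_of(tip: str) -> str:
        s = statuses.get(tip)
        if s is None:
            return UNKNOWN
        return s if isinstance(s, str) else s.status

    relevant = [
        a for a in assignments
        if a.group.inactivating and (gene is None or a.group.key.gene == gene)
    ]
    genes = {a.group.key.gene for a in relevant}
    if gene is None and len(genes) > 1:
        raise ValueError("assignments span several genes; pass gene=...")

    candidates: dict[Branch, list[LesionGroup]] = {}
    for a in relevant:
        for b in a.branches:
            candidates.setdefault(b, []).append(a.group)
    kept = []
    for b in candidates:
        desc = tree.tips_below(b.child)
        known = [t for t in desc if status_of(t) != UNKNOWN]
        if known and all(status_of(t) == PSEUDOGENE for t in known):
            kept.append(b)
    maximal = [
        b for b in kept
        if not any(
            other != b and tree.is_descendant(b.child, other.child)
            for other in kept
        )
    ]
    events = []
    gene_name = gene or (next(iter(genes)) if genes else "")
    for b in sorted(maximal, key=lambda b: (-tree.age(b.child), b.child)):
        lo, hi = tree.branch_interval(b)
        events.append(
            LossEvent(
                gene=gene_name,
                branch=b,
                interval_mya=(lo, hi),
                causal_groups=sorted(candidates[b], key=lambda g: g.key),
                predicted_tips=sorted(tree.tips_below(b.child)),
            )
        )
    return events


def predict_unsampled_status(
    event: LossEvent, tip: str, tree: TimeTree
) -> Optional[str]:
    """Predicted status for a tree tip under a loss event.

    Returns ``"pseudogene"`` when the tip descends from the loss branch's
    child (sampled or not); ``None`` (no prediction) otherwise.
    """
    if tip not in tree or not tree.is_tip(tip):
        raise LabelError(f"tip {tip!r} not in tree")
    return PSEUDOGENE if tip in event.predicted_tips else None
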