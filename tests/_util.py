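"""Shared test helpers: fixture builders and independent brute-force oracles.

The oracles here deliberately avoid the package's own coordinate machinery:
the downstream-stop oracle applies an indel by plain string surgery and
translates linearly; the Dollo oracle searches edge subsets exhaustively.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from pseudotrace import ExonSpec, GeneModel
from pseudotrace.alignment import STOP_CODONS
from pseudotrace.simulate import SENSE_CODONS

# ---------------------------------------------------------------------------
# sequence fixtures
# ---------------------------------------------------------------------------

def random_sense_cds(n_codons: int, rng: np.random.Generator,
                     stop: str = "TAA") -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx) + stop


def single_exon_model(gene: str, length: int) -> GeneModel:
    return GeneModel(gene, [ExonSpec("exon1", length, 0)])


def translate_codons(seq: str) -> list[str]:
    return [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


# ---------------------------------------------------------------------------
# brute-force downstream premature-stop oracle (single-exon gene)
# ---------------------------------------------------------------------------

def oracle_downstream_stop(ref: str, kind: str, position: int,
                           seq: str = "", length: int = 0):
    """Apply the indel by string surgery, translate linearly from the codon
    containing the frameshift, and map the first stop back to reference
    coordinates.  Returns (triplet, (start, end)) with None components for
    inserted bases, or None when no stop precedes the CDS end (or the first
    in-frame stop is the native terminal stop).
    """
    L = len(ref)
    if kind == "insertion":
        a = position  # insertion between a and a+1 (1-based)
        target = ref[:a] + seq + ref[a:]
        i0 = a
        m = len(seq)

        def refpos(t):
            if t < a:
                return t + 1
            if t < a + m:
                return None
            return t - m + 1
    else:  # deletion of `length` bases starting at `position`
        d = position
        target = ref[:d - 1] + ref[d - 1 + length:]
        i0 = d - 1

        def refpos(t):
            return t + 1 if t < d - 1 else t + length + 1

    native = {L - 2, L - 1, L}
    start = (i0 // 3) * 3
    for c in range(start, len(target) - 2, 3):
        triplet = target[c:c + 3]
        if triplet not in STOP_CODONS:
            continue
        spots = {refpos(c + k) for k in range(3)}
        if spots == native:
            return None
        return triplet, (refpos(c), refpos(c + 2))
    return None


# ---------------------------------------------------------------------------
# rooted binary topology enumeration + exhaustive Dollo oracle
# ---------------------------------------------------------------------------

def _insertions(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def all_rooted_topologies(labels):
    """All rooted binary leaf-labelled topologies on the given labels."""
    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [t for tr in trees for t in _insertions(tr, lab)]
    return trees


def topology_to_newick(tree) -> str:
    """Ultrametric Newick: node heights are max subtree depth in unit steps."""
    def height(t):
        if isinstance(t, str):
            return 0
        return max(height(t[0]), height(t[1])) + 1

    def rec(t, parent_h):
        if isinstance(t, str):
            return f"{t}:{parent_h}"
        h = height(t)
        return f"({rec(t[0], h)},{rec(t[1], h)}):{parent_h - h}"

    h = height(tree)
    return f"({rec(tree[0], h)},{rec(tree[1], h)});"


def clade_masks(tree, bit):
    """Bitmasks of every clade (one per edge, including the root edge)."""
    masks = []

    def rec(t):
        if isinstance(t, str):
            m = bit[t]
        else:
            m = rec(t[0]) | rec(t[1])
        masks.append(m)
        return m

    rec(tree)
    return masks


def oracle_min_origins(masks, carriers_mask) -> int:
    """Minimal number of edges whose clades partition the carrier set,
    by exhaustive search over candidate-edge subsets."""
    cands = sorted({m for m in masks if m and m & carriers_mask == m})
    n_bits = bin(carriers_mask).count("1")
    for k in range(1, n_bits + 1):
        for combo in combinations(cands, k):
            u = 0
            for m in combo:
                u |= m
            if u == carriers_mask:
                return k
    raise AssertionError("carrier set not coverable by clades")
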