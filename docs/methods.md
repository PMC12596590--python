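# Methods

## Coordinate model

Lesions are reported in per-exon reference coordinates: 1-based, counted
from the 5′ end of each exon separately, left to right. A column of an
exon alignment counts as a reference position if **any** reference-role row
is non-gap there. This permissive rule is a genuine design choice: when
several jointly aligned reference species disagree in gap pattern there is
no unambiguous convention, and anchoring on the union keeps numbering
robust to which reference happens to carry a micro-indel. Columns gapped
in all reference rows are insertion slots "between *p* and *p*+1", with an
ordinal offset along a run of such columns. The gap character is fixed to
`-` and `.` is rejected outright; accepting both silently is a classic
source of corrupt alignments.

The gene model carries exon order, reference lengths and entry phases; the
reading frame is continuous across junctions (codons may span them), and
the model is validated against the alignments (span per exon, phase chain,
a stop codon at the annotated native stop in at least one reference row).

## Lesion classification

Four inactivating classes are recognised, matching how pseudogene surveys
count mutations:

* **Nonsense substitution.** Called per codon: at least one target base
  differs from every reference allele at its site, the codon built with the
  mutant allele(s) is TAA/TAG/TGA, no single reference row spells a stop at
  the same triplet, and the triplet precedes the native stop. Sites where
  the references are themselves polymorphic are still callable — the
  target allele must simply be absent from all of them. A stop at the
  native stop position is never a lesion.
* **Stop-carrying insertion.** The inserted bases are read in the frame
  entering the insertion (carried bases from the current codon, then the
  insert); a stop triplet lying entirely within the inserted bases makes
  the record a `stop_insertion`, tallied with the nonsense class regardless
  of length mod 3 — this is how a long stop-bearing insertion is counted in
  the field. A stop formed partly from flanking bases is deliberately
  *not* classified here; a short insertion creating such a stop is a
  frameshift whose premature stop the downstream scan then reports.
* **Frameshift insertion/deletion.** Maximal runs of target-only inserted
  columns, or of reference positions gapped in the target, with length ≢ 0
  (mod 3). Runs are broken by any matched column and at exon junctions.
  For each frameshift the target's own gap-stripped CDS is translated from
  the codon containing the shift — its frame therefore reflects every
  upstream indel of that target — across junctions and through any
  subsequent indels, until the first stop or the CDS end. The stop is
  mapped back through the coordinate map, so inserted bases consume no
  reference positions. If the first in-frame stop reached is the native
  terminal stop, no premature stop is reported.
* **In-frame indel** (length ≡ 0 mod 3, no inserted stop): recorded,
  flagged non-inactivating.

Nonsense calling always uses the reference frame, including downstream of a
target frameshift. On real decayed pseudogenes this can count a
substitution that is only a stop in the ancestral frame; surveys count
exactly this way, and the simulator's truth log accounts for it (below).

**Zygosity.** Sanger-style: a plain base differing from all reference
alleles is homozygous; a 2-fold IUPAC code containing one reference and one
non-reference allele is heterozygous; 3- and 4-fold codes (N, B, D, H, V)
are uninformative and yield no call, as does a 2-fold code with no
reference allele (two mutant readings cannot be separated).

## Status calls

Pseudogene iff ≥ 1 inactivating record; `unknown` is reserved for unscanned
taxa. Heterodimeric receptors use the obligate-dimer rule: nonfunctional
iff any component gene is a pseudogene, functional iff all are intact, else
unknown. "Severe reduction" is collapsed into the binary nonfunctional
call, and an unknown component never improves a receptor call — a
deliberately conservative choice for prediction.

## Dollo mapping and loss dating

Trees are rooted, ultrametric (relative root-to-tip deviation ≤ 1e-6) with
branch lengths in My; node ages are root height minus depth. Lesion
identity for grouping is (gene, exon, location, class, alt allele, indel
length).

Under the Dollo assumption — an inactivating lesion, once fixed, is never
reverted, the standard reading for pseudogene lesions — each group's
origins are the stem branches of the maximal clades in which every
*sampled* tip is a carrier. This attains the minimum origin count
(verified against exhaustive edge-cover search on all topologies with ≤ 6
tips); more than one origin is reported as homoplasy rather than silently
discarded, so the "independent losses" alternative is always representable.
Unsampled tips are ordinary tree tips without reports: they never veto an
origin and never enter counts, and predictions about them are explicit.

The loss branch for a gene is the assigned branch closest to the root whose
known-status descendants are all pseudogenes; assigned branches nested
under it (e.g. later species-specific nonsense mutations) are absorbed.
Each surviving branch yields one loss event with interval
[age(child), age(parent)] Mya and the full descendant tip list as predicted
nonfunctional. If the root's own edge carries the origin the upper
endpoint is clamped to the root age (losses cannot be dated beyond the
tree). Ties between equally rootward candidates are resolved rootward;
this can only occur with unknown-status intervening tips.

## Simulator

The generator's defaults describe the study situation it emulates:
functional references plus a clade in which one branch loses constraint.

* Reference CDS: uniform-random sense codons plus a terminal stop;
  partitioned into exons with chained phases.
* Substitutions: per-branch Poisson at μ substitutions/site/My, equal
  exchange among the three alternative bases (Jukes–Cantor-style; the
  simplest one-parameter process that serves the pipeline).
* Purifying constraint on functional lineages: rejection sampling — any
  proposed substitution creating an internal stop (or destroying the
  terminal stop) is discarded, and indels are forbidden by default
  (an option allows rare in-frame, stop-free insertions). Rejection, not
  rate rescaling, makes the zero-false-positive property exact.
* On the loss branch and its descendants: all substitutions accepted;
  indels at ι events/site/My, insertion/deletion equiprobable, lengths
  geometric with mean 2 bp; inserted columns get globally ordered keys so
  descendants that inherit an insertion share alignment columns.
* One seeded generator, branches visited in preorder: a fixed (config,
  seed) reproduces alignments and truth log byte-for-byte. Substitutions
  are applied before indels within a branch.

The truth log records every applied event. Its `inactivating` flag is an
*upper bound* on detectability: substitutions are flagged when the new base
completes a stop in **any** frame, insertions when length ≢ 0 (mod 3) or
the insert contains a stop in any frame. This over-flagging is what makes
the conservation invariant (records detected on a tip ≤ flagged events on
its root path; detection may merge adjacent events, never invent) hold even
for reference-frame nonsense calls downstream of frameshifts.

What the simulator does **not** emulate: codon-usage and base-composition
bias, rate heterogeneity across sites and branches, alignment error
(alignments are true by construction), sequencing gaps and heterozygous
indels. Passing tests therefore demonstrate correctness of the inference
chain under idealised alignments, not robustness to alignment artefacts.

## Worked-example fixtures

The demo bundle rebuilds a published six-lesion catalogue (two taste
receptor genes, two carrier species, three references) over a synthetic
background: exon lengths are plausible stand-ins chosen to satisfy the
published per-exon coordinates and phases (TAS1R1: 267, 156, 297, 300,
118, 935 bp; TAS1R3: 219, 144, 720, 300, 180, 390 bp), and the
lesion-bearing neighbourhoods are pinned (the codons hit by the nonsense
substitutions; a T-free zone in exon 6 positions 693–932 so that the only
shifted-frame stop after the 693/694 frameshift is the TAG pinned at
746–748 and the 823/824 frameshift meets none). The long exon-4 insertion
is 213 bp — the published account reports only its termini and a length
"> 210 bp"; 213 keeps it a multiple of 3 so it does not compound a
frameshift. The grison's TAS1R3 is treated as intact by default (its
sequence comes from earlier work and no lesions are described); this is an
explicit flag on the bundle, not an inference. The fixture tree fixes only
the two constrained ages (Lyncodontini crown 3.0 Mya, its parent 9.5 Mya);
the remaining ages and the dog outgroup at 45 Mya are placeholders that do
not affect the dated interval.

## Problem sizes and acceptance checks

`scripts/acceptance.py` and the acceptance tests use desk-scale problems
chosen as the smallest sizes that exercise each property convincingly:
the full ~2 kb demo genes for the printed tallies and coordinates; 100
random planted-frameshift fixtures (40–200 codons) against the
string-surgery translation oracle; all 1 069 rooted binary topologies with
2–6 tips × all carrier subsets against the exhaustive Dollo oracle; 200
intact 4-tip clades (100 codons, μ ≤ 0.02) for false-positive control; and
200 replicates of the recovery experiment — 150 codons on
`((A:1,B:1):2,(C:2,D:2):1)` with the loss planted on the internal branch,
μ = 0.02, ι = 0.004 (expected post-loss inactivating events per descendant
≈ 5), requiring the planted branch to be recovered in ≥ 95% of replicates.
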