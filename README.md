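# pseudotrace

Pseudogene lesion detection and gene-loss dating for exon-wise
coding-sequence alignments.

Comparative studies of sensory gene loss — taste receptors in carnivorans
being a canonical case — rest on a small, well-defined inference chain:
find the mutations that wreck a gene's open reading frame, decide which
genes are pseudogenes, note which lesions are shared between species, place
each lesion's origin on a dated phylogeny, and read off when the gene (and
any obligate heterodimeric receptor it contributes to) must have stopped
working. `pseudotrace` implements that chain as a tested, reusable library
and command-line pipeline, aimed at molecular evolutionists who have
per-exon CDS alignments (reference species plus candidate pseudogene
carriers) and a time-calibrated tree.

## What it computes

**Lesion detection.** Within each exon, coordinates are 1-based reference
positions counted from the exon's 5′ end; columns gapped in every reference
row are insertion slots "between *p* and *p*+1". With the reading frame
carried across exon junctions (exon phases from a gene model), the scanner
reports, per target taxon:

- *nonsense substitutions* — the target base differs from every reference
  allele and the in-frame codon becomes TAA/TAG/TGA before the native stop;
- *stop-carrying insertions* — inserted bases, read in the entering frame,
  contain a stop triplet (tallied with the nonsense class);
- *frameshift insertions/deletions* — indel length ≢ 0 (mod 3); the first
  premature stop downstream in the shifted frame is located and mapped back
  to reference coordinates (inserted bases consume no reference positions);
- *in-frame indels* — recorded but non-inactivating.

Zygosity is read from IUPAC ambiguity codes (a 2-fold code containing a
reference and a mutant allele is a heterozygous call).

**Status calls.** A gene with ≥ 1 inactivating lesion is a pseudogene.
For an obligate heterodimer R = (G₁, G₂), R is nonfunctional iff either
component is a pseudogene, functional iff both are intact, else unknown.

**Dollo mapping and dating.** Identical lesions are grouped across taxa;
each group's origin is assigned under Dollo parsimony (a lesion arises once
and never reverts): the stem branch of each maximal clade whose sampled
tips all carry it, with multiple origins flagged as homoplasy. The loss
branch for a gene is the assigned branch closest to the root whose sampled
descendants are all pseudogenes; the loss is bracketed by
[age(child), age(parent)] in Mya, and all descendant tips — including
unsampled ones — are listed as predicted nonfunctional.

**Simulation.** A synthetic-data module generates functional CDS
alignments and evolves them along a dated tree (Jukes–Cantor-style
substitutions; purifying constraint by rejection sampling outside a planted
loss branch; free substitutions plus geometric-length indels after it),
with a complete ground-truth event log for power and false-positive tests.

## Worked example

The bundled example reconstructs a published lesion catalogue: loss of the
TAS1R1–TAS1R3 umami receptor in the Lyncodontini (Patagonian weasel
*Lyncodon patagonicus* and lesser grison *Galictis cuja*), scanned against
the dog and two non-Lyncodontini ictonychine polecats as references.

```bash
pseudotrace demo --out bundle
pseudotrace detect --alignments bundle --gene-model bundle/gene_models.json \
    --roles bundle/roles.yaml --out det
pseudotrace map --reports det/reports --tree bundle/tree.nwk \
    --receptors bundle/receptors.yaml --out mapped
```

`det/mutations.tsv` (insertion sequence truncated for display):

```
taxon                 gene    exon   class                  location  ref  alt  len  zygosity    stop  span
Galictis_cuja         TAS1R1  exon4  nonsense_substitution  10        C    T    0    homozygous  TAG   10-12
Galictis_cuja         TAS1R1  exon6  frameshift_insertion   693^694   .    A    1    homozygous  TAG   746-748
Galictis_cuja         TAS1R1  exon6  frameshift_insertion   823^824   .    C    1    homozygous  .     .
Lyncodon_patagonicus  TAS1R1  exon3  nonsense_substitution  295       C    T    0    homozygous  TGA   295-297
Lyncodon_patagonicus  TAS1R1  exon4  stop_insertion         57^58     .    GTG…  213 homozygous  TAA   .
Lyncodon_patagonicus  TAS1R1  exon6  frameshift_insertion   693^694   .    A    1    homozygous  TAG   746-748
Lyncodon_patagonicus  TAS1R1  exon6  frameshift_insertion   823^824   .    C    1    homozygous  .     .
Lyncodon_patagonicus  TAS1R3  exon3  nonsense_substitution  690       C,T  G    0    homozygous  TAG   688-690
```

Reading: the weasel's *TAS1R1* carries 2 nonsense-type and 2 frameshift
mutations, the grison's 1 and 2, and the weasel's *TAS1R3* 1 nonsense
mutation — so all three genes are pseudogenes. The two exon-6 1-bp
insertions are identical in both species (same slot, same base), so the
mapper places their origin on the Lyncodontini stem:

```
gene    parent        child         age_lo_mya  age_hi_mya  n_causal_groups  predicted_tips
TAS1R1  Ictonychinae  Lyncodontini  3           9.5         2                Galictis_cuja,Galictis_vittata,Lyncodon_patagonicus
TAS1R3  Lyncodontini  Lyncodon_patagonicus  0   3           1                Lyncodon_patagonicus
```

i.e. *TAS1R1* — and with it the TAS1R1–TAS1R3 umami receptor — was lost
between 3 and 9.5 Mya in the common ancestor of the tribe, which predicts
nonfunctionality in the unsampled greater grison *Galictis vittata*;
the species-specific nonsense mutations arose later on the terminal
branches. `mapped/receptor_status.json` additionally reports the weasel's
sweet receptor (TAS1R2–TAS1R3) as nonfunctional via the shared TAS1R3
subunit.

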