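"""Lesion detector: nonsense, indels, zygosity, downstream stops, scanning."""

import numpy as np
import pytest

from pseudotrace import (
    ClassificationError,
    LesionSpec,
    TaxonError,
    concatenate_gene,
    detect_indels,
    detect_nonsense_substitutions,
    locate_downstream_premature_stop,
    plant_fixture_mutations,
    scan_gene,
)
from pseudotrace.lesions import (
    FRAMESHIFT_DELETION,
    FRAMESHIFT_INSERTION,
    HETEROZYGOUS,
    HOMOZYGOUS,
    INFRAME_INDEL,
    NONSENSE_SUBSTITUTION,
    STOP_INSERTION,
    call_zygosity,
)
from pseudotrace.simulate import SENSE_CODONS

from _util import oracle_downstream_stop, random_sense_cds, single_exon_model

REFS = ("dog", "polecat")


def planted_view(cds, model, lesions, **kw):
    alns = plant_fixture_mutations(cds, model, lesions, REFS, **kw)
    return concatenate_gene(alns, model)


class TestNonsenseSubstitutions:
    def test_stop_creating_substitution_reported_with_span(self):
        # CGA codon at positions 7-9; C→T makes TGA
        cds = "ATGGCC" + "CGA" + "GCCGGG" + "TAA"
        model = single_exon_model("g", 18)
        view = planted_view(cds, model,
                            [LesionSpec("substitution", "exon1", 7, ("w",), seq="T")])
        recs = detect_nonsense_substitutions(view, "w")
        assert len(recs) == 1
        r = recs[0]
        assert r.klass == NONSENSE_SUBSTITUTION
        assert r.location.pos == 7
        assert r.zygosity == HOMOZYGOUS
        assert r.premature_stop.triplet == "TGA"
        assert (r.premature_stop.span[0].pos, r.premature_stop.span[1].pos) == (7, 9)

    def test_polymorphic_reference_site_still_called(self):
        # refs carry TAC (dog) / TAT (polecat) at 7-9; target G at 9 -> TAG
        cds = "ATGGCC" + "TAC" + "GCCGGG" + "TAA"
        model = single_exon_model("g", 18)
        view = planted_view(
            cds, model,
            [LesionSpec("substitution", "exon1", 9, ("w",), seq="G")],
            reference_overrides={("exon1", 9): {"polecat": "T"}},
        )
        recs = detect_nonsense_substitutions(view, "w")
        assert len(recs) == 1
        assert recs[0].ref_alleles == frozenset("CT")
        assert recs[0].premature_stop.triplet == "TAG"
        assert (recs[0].premature_stop.span[0].pos,
                recs[0].premature_stop.span[1].pos) == (7, 9)

    def test_target_allele_matching_any_reference_is_silent(self):
        cds = "ATGGCC" + "TAC" + "GCCGGG" + "TAA"
        model = single_exon_model("g", 18)
        # target T at position 9 equals the polecat allele: not a mutation
        view = planted_view(
            cds, model,
            [LesionSpec("substitution", "exon1", 9, ("w",), seq="T")],
            reference_overrides={("exon1", 9): {"polecat": "T"}},
        )
        assert detect_nonsense_substitutions(view, "w") == []

    def test_substitution_at_native_stop_is_not_a_lesion(self):
        cds = "ATGGCCGCA" + "TAA"
        model = single_exon_model("g", 12)
        # TAA -> TGA at the terminal codon: still the native stop
        view = planted_view(cds, model,
                            [LesionSpec("substitution", "exon1", 11, ("w",), seq="G")])
        assert detect_nonsense_substitutions(view, "w") == []

    def test_identical_target_yields_nothing(self):
        cds = "ATGGCCGCA" + "TAA"
        model = single_exon_model("g", 12)
        view = planted_view(cds, model, [], target_taxa=("w",))
        assert scan_gene(view, target="w").records == []

    def test_missing_taxon_raises(self):
        cds = "ATGGCCGCA" + "TAA"
        model = single_exon_model("g", 12)
        view = planted_view(cds, model, [], target_taxa=("w",))
        with pytest.raises(TaxonError):
            detect_nonsense_substitutions(view, "nosuch")

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_stop_agrees_with_translation_oracle(self, seed):
        """A random stop-creating substitution in a 200-codon gene is found
        exactly where codon-by-codon translation says it changed to a stop."""
        rng = np.random.default_rng(seed)
        cds = random_sense_cds(200, rng)
        model = single_exon_model("g", 603)
        # choose a codon that one substitution turns into a stop
        while True:
            c = int(rng.integers(199))
            codon = cds[3 * c:3 * c + 3]
            hits = [
                (k, b)
                for k in range(3)
                for b in "ACGT"
                if b != codon[k]
                and codon[:k] + b + codon[k + 1:] in ("TAA", "TAG", "TGA")
            ]
            if hits:
                k, b = hits[int(rng.integers(len(hits)))]
                pos = 3 * c + k + 1
                break
        view = planted_view(cds, model,
                            [LesionSpec("substitution", "exon1", pos, ("w",), seq=b)])
        recs = detect_nonsense_substitutions(view, "w")
        assert len(recs) == 1
        # oracle: translate target against reference, find the changed stop
        target = cds[:pos - 1] + b + cds[pos:]
        changed = [
            i for i in range(200)
            if target[3 * i:3 * i + 3] in ("TAA", "TAG", "TGA")
            and cds[3 * i:3 * i + 3] not in ("TAA", "TAG", "TGA")
        ]
        assert changed == [c]
        assert (recs[0].premature_stop.span[0].pos - 1) // 3 == c


class TestIndels:
    def test_insertion_with_fully_inserted_stop_is_stop_insertion(self):
        cds = "ATGGCC" + "GCAGGG" + "TAA"
        model = single_exon_model("g", 15)
        # 6-bp insertion at the codon boundary after position 6: GCC TAA
        view = planted_view(cds, model,
                            [LesionSpec("insertion", "exon1", 6, ("w",), seq="GCCTAA")])
        recs = detect_indels(view, "w")
        assert [r.klass for r in recs] == [STOP_INSERTION]
        assert recs[0].premature_stop.triplet == "TAA"
        assert recs[0].location.key() == "6^7"

    def test_one_bp_insertion_is_frameshift(self):
        cds = "ATGGCCGCAGGG" + "TAA"
        model = single_exon_model("g", 15)
        view = planted_view(cds, model,
                            [LesionSpec("insertion", "exon1", 7, ("w",), seq="A")])
        recs = detect_indels(view, "w")
        assert [r.klass for r in recs] == [FRAMESHIFT_INSERTION]
        assert recs[0].indel_length == 1

    def test_inframe_insertion_without_stop_is_non_inactivating(self):
        cds = "ATGGCCGCAGGG" + "TAA"
        model = single_exon_model("g", 15)
        view = planted_view(cds, model,
                            [LesionSpec("insertion", "exon1", 6, ("w",), seq="GCC")])
        recs = detect_indels(view, "w")
        assert [r.klass for r in recs] == [INFRAME_INDEL]
        assert not recs[0].inactivating

    def test_two_bp_deletion_is_frameshift(self):
        cds = "ATGGCCGCAGGG" + "TAA"
        model = single_exon_model("g", 15)
        view = planted_view(cds, model,
                            [LesionSpec("deletion", "exon1", 7, ("w",), length=2)])
        recs = detect_indels(view, "w")
        assert [r.klass for r in recs] == [FRAMESHIFT_DELETION]
        assert recs[0].indel_length == 2
        assert recs[0].location.key() == "7..8"

    def test_indels_separated_by_matched_column_stay_distinct(self):
        cds = "ATGGCCGCAGGGCCA" + "TAA"
        model = single_exon_model("g", 18)
        view = planted_view(cds, model, [
            LesionSpec("deletion", "exon1", 4, ("w",), length=1),
            LesionSpec("deletion", "exon1", 6, ("w",), length=1),
        ])
        recs = detect_indels(view, "w")
        assert [r.location.key() for r in recs] == ["4..4", "6..6"]


class TestZygosity:
    @pytest.mark.parametrize("residue,refs,expected", [
        ("T", {"C"}, (HOMOZYGOUS, ("T",))),
        ("Y", {"C"}, (HETEROZYGOUS, ("T",))),   # Y = C/T
        ("N", {"C"}, None),                      # uninformative
        ("C", {"C"}, None),                      # matches reference
        ("T", {"Y"}, None),                      # inside reference expansion
        ("K", {"C"}, None),                      # two non-reference alleles
        ("R", {"A", "T"}, (HETEROZYGOUS, ("G",))),
    ])
    def test_zygosity_calls(self, residue, refs, expected):
        assert call_zygosity(residue, refs) == expected

    def test_heterozygous_nonsense_is_reported_heterozygous(self):
        cds = "ATGGCC" + "CGA" + "GCCGGG" + "TAA"
        model = single_exon_model("g", 18)
        alns = plant_fixture_mutations(cds, model, [], REFS, target_taxa=("w",))
        # overwrite the target base with the C/T ambiguity by hand
        from pseudotrace.alignment import AlignedRow, ExonAlignment
        rows = []
        for r in alns[0].rows:
            seq = r.seq[:6] + "Y" + r.seq[7:] if r.taxon == "w" else r.seq
            rows.append(AlignedRow(r.taxon, r.role, seq))
        view = concatenate_gene([ExonAlignment("exon1", rows)], model)
        recs = detect_nonsense_substitutions(view, "w")
        assert len(recs) == 1
        assert recs[0].zygosity == HETEROZYGOUS
        assert recs[0].premature_stop.triplet == "TGA"


class TestDownstreamStop:
    def _fixture(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 170))
        cds = random_sense_cds(n, rng)
        L = len(cds)
        if rng.random() < 0.5:
            kind = "insertion"
            pos = int(rng.integers(1, L - 3))
            m = int(rng.integers(1, 3))
            seq = "".join("ACGT"[int(b)] for b in rng.integers(4, size=m))
            lesion = LesionSpec(kind, "exon1", pos, ("w",), seq=seq)
            oracle = oracle_downstream_stop(cds, kind, pos, seq=seq)
        else:
            kind = "deletion"
            m = int(rng.integers(1, 3))
            pos = int(rng.integers(1, L - 3 - m))
            lesion = LesionSpec(kind, "exon1", pos, ("w",), length=m)
            oracle = oracle_downstream_stop(cds, kind, pos, length=m)
        model = single_exon_model("g", L)
        view = planted_view(cds, model, [lesion])
        return view, oracle

    @pytest.mark.parametrize("seed", range(50))
    def test_shifted_frame_stop_matches_string_surgery_oracle(self, seed):
        view, oracle = self._fixture(seed)
        recs = [r for r in detect_indels(view, "w")
                if r.klass in (FRAMESHIFT_INSERTION, FRAMESHIFT_DELETION)]
        assert len(recs) == 1
        ps = locate_downstream_premature_stop(view, "w", recs[0])
        if oracle is None:
            assert ps is None
        else:
            triplet, (start, end) = oracle
            assert ps is not None
            assert ps.triplet == triplet
            if start is None or end is None:
                assert ps.span is None
            else:
                assert (ps.span[0].pos, ps.span[1].pos) == (start, end)

    def test_compensated_frameshift_with_no_stop_returns_none(self):
        # +1 insertion then a later +2 insertion; intervening shifted frame
        # is free of T so no stop can form before the CDS end
        cds = "ATG" + "CAC" * 8 + "TAA"
        model = single_exon_model("g", 30)
        view = planted_view(cds, model, [
            LesionSpec("insertion", "exon1", 5, ("w",), seq="A"),
            LesionSpec("insertion", "exon1", 20, ("w",), seq="CA"),
        ])
        recs = [r for r in detect_indels(view, "w")
                if r.klass == FRAMESHIFT_INSERTION]
        assert len(recs) == 2
        for r in recs:
            assert locate_downstream_premature_stop(view, "w", r) is None

    def test_stop_scan_continues_across_exon_junction(self):
        # frameshift near the end of exon 1; first shifted stop in exon 2
        from pseudotrace import ExonSpec, GeneModel
        cds = "ATGCACCAC" + "CCTAGCCACCACTAA"
        model = GeneModel("g", [ExonSpec("e1", 9, 0), ExonSpec("e2", 15, 0)])
        view = planted_view(cds, model,
                            [LesionSpec("insertion", "e1", 6, ("w",), seq="C")])
        recs = [r for r in detect_indels(view, "w")
                if r.klass == FRAMESHIFT_INSERTION]
        ps = locate_downstream_premature_stop(view, "w", recs[0])
        assert ps is not None
        assert ps.exon_id == "e2"

    def test_non_frameshift_record_rejected(self):
        cds = "ATGGCCGCAGGG" + "TAA"
        model = single_exon_model("g", 15)
        view = planted_view(cds, model,
                            [LesionSpec("insertion", "exon1", 6, ("w",), seq="GCC")])
        recs = detect_indels(view, "w")
        with pytest.raises(ClassificationError):
            locate_downstream_premature_stop(view, "w", recs[0])


class TestScanGene:
    def test_records_sorted_and_counts_match_multiset(self):
        cds = "ATGGCC" + "CGA" + "GCCGGGCCAGCA" + "TAA"
        model = single_exon_model("g", 24)
        view = planted_view(cds, model, [
            LesionSpec("insertion", "exon1", 13, ("w",), seq="A"),
            LesionSpec("substitution", "exon1", 7, ("w",), seq="T"),
        ])
        rep = scan_gene(view, target="w")
        assert [r.klass for r in rep.records] == [
            NONSENSE_SUBSTITUTION, FRAMESHIFT_INSERTION
        ]
        assert rep.counts == {"nonsense": 1, "frameshift": 1, "inframe": 0}

    def test_coordinates_invariant_to_upstream_foreign_insertion(self):
        """Another taxon's upstream insertion shifts columns but must not
        move this taxon's reported reference coordinates."""
        cds = "ATGGCC" + "CGA" + "GCCGGGCCAGCA" + "TAA"
        model = single_exon_model("g", 24)
        lesions = [LesionSpec("substitution", "exon1", 7, ("w",), seq="T"),
                   LesionSpec("insertion", "exon1", 13, ("w",), seq="A")]
        plain = scan_gene(
            plant_fixture_mutations(cds, model, lesions, REFS), model, "w"
        )
        shifted = scan_gene(
            plant_fixture_mutations(
                cds, model,
                [LesionSpec("insertion", "exon1", 2, ("v",), seq="GGGG")] + lesions,
                REFS,
            ),
            model, "w",
        )
        assert [r.location.key() for r in plain.records] == \
               [r.location.key() for r in shifted.records]
        assert [r.premature_stop and r.premature_stop.to_dict()
                for r in plain.records] == \
               [r.premature_stop and r.premature_stop.to_dict()
                for r in shifted.records]

    def test_counts_invariant_to_row_order(self):
        cds = "ATGGCC" + "CGA" + "GCCGGGCCAGCA" + "TAA"
        model = single_exon_model("g", 24)
        lesions = [LesionSpec("substitution", "exon1", 7, ("w",), seq="T")]
        a = plant_fixture_mutations(cds, model, lesions, REFS)
        from pseudotrace.alignment import ExonAlignment
        flipped = [ExonAlignment(x.exon_id, list(reversed(x.rows))) for x in a]
        assert scan_gene(a, model, "w").counts == \
               scan_gene(flipped, model, "w").counts
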