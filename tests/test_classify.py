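"""Hit screening, alignment identity, PROSITE matching and family assignment."""

import numpy as np
import pytest

from aldh_curator import synthetic
from aldh_curator.alignment import global_identity
from aldh_curator.classify import (
    FamilyAssignment,
    HomologyHit,
    LabeledProtein,
    assign_families,
    filter_candidate_hits,
    name_genes,
)
from aldh_curator.errors import PatternError, SequenceError, ValidationError
from aldh_curator.prosite import compile_pattern, match_prosite_pattern

from oracles import max_identity_over_optimal_alignments

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestHitFilter:
    def test_all_thresholds_satisfied_retained(self):
        hit = HomologyHit("q", "s", 30.0, 40.0, 1e-30)
        assert filter_candidate_hits([hit]) == [hit]

    def test_identity_below_cutoff_dropped(self):
        assert filter_candidate_hits([HomologyHit("q", "s", 24.9, 90.0, 0.0)]) == []

    def test_evalue_direction_is_significance(self):
        # printed-threshold direction: small E-values pass, large fail
        assert filter_candidate_hits([HomologyHit("q", "s", 50.0, 50.0, 1e-10)]) == []

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValidationError):
            filter_candidate_hits([HomologyHit("q", "s", 50.0, 50.0, -1.0)])

    def test_matches_per_record_bruteforce_on_random_hits(self):
        rng = np.random.default_rng(42)
        hits = [
            HomologyHit(
                f"q{i}", "s",
                float(rng.uniform(0, 100)),
                float(rng.uniform(0, 100)),
                float(10.0 ** rng.uniform(-40, 0)),
            )
            for i in range(100)
        ]
        expected = [h for h in hits if h.query_coverage >= 25 and h.pct_identity >= 25 and h.e_value <= 1e-25]
        assert filter_candidate_hits(hits) == expected


class TestGlobalIdentity:
    def test_identical_sequences_are_100(self):
        assert global_identity("MKVLA", "MKVLA") == 100.0

    def test_single_substitution_nonamer_matches_enumeration_oracle(self):
        a, b = "ACDEFGHIK", "ACDEFGHIR"
        assert global_identity(a, b) == pytest.approx(max_identity_over_optimal_alignments(a, b))

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = "".join(rng.choice(AA, 30))
            b = "".join(rng.choice(AA, 25))
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_x_never_counts_as_match(self):
        assert global_identity("AXA", "AXA") == pytest.approx(100.0 * 2 / 3)

    def test_agrees_with_enumeration_oracle_on_short_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(AA, la))
            b = "".join(rng.choice(AA, lb))
            assert global_identity(a, b) == pytest.approx(
                max_identity_over_optimal_alignments(a, b)
            ), (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            global_identity("", "ACD")

    def test_illegal_character_named(self):
        with pytest.raises(SequenceError, match="'J'"):
            global_identity("AJC", "ACD")


class TestPrositeMatching:
    def test_simple_pattern_finds_all_nonoverlapping_matches(self):
        assert match_prosite_pattern("AXCAAC", "A-x-C") == [(1, 3), (4, 6)]

    def test_alternative_set_with_repetition(self):
        assert match_prosite_pattern("GTTC", "[AG]-x(2)-C") == [(1, 4)]

    def test_no_occurrence_gives_empty_list(self):
        assert match_prosite_pattern("GGGG", "A") == []

    def test_exclusion_set(self):
        assert match_prosite_pattern("ACG", "A-{P}-G") == [(1, 3)]
        assert match_prosite_pattern("APG", "A-{P}-G") == []

    def test_anchors(self):
        assert match_prosite_pattern("MAC", "<M-A") == [(1, 2)]
        assert match_prosite_pattern("AMA", "<M-A") == []
        assert match_prosite_pattern("CAG", "A-G>") == [(2, 3)]
        assert match_prosite_pattern("AGC", "A-G>") == []

    def test_variable_repetition_range(self):
        # x(1,2) is greedy but leftmost: on 'ACCG' the first match spans 1-4
        assert match_prosite_pattern("ACCG", "A-x(1,2)-G") == [(1, 4)]

    @pytest.mark.parametrize("bad", ["A--C", "[AC", "A-(3)", "A-x(1,", "A-B"])
    def test_malformed_patterns_raise_with_position(self, bad):
        with pytest.raises(PatternError) as err:
            compile_pattern(bad)
        assert err.value.position is not None


class TestAssignFamilies:
    def test_identical_to_reference_joins_its_subfamily(self):
        seq = "".join(np.random.default_rng(0).choice(AA, 80))
        refs = [LabeledProtein("ref", seq, 3, "H")]
        (a,) = assign_families({"p": seq}, refs)
        assert (a.family, a.subfamily) == (3, "H")
        assert a.evidence == 100.0

    def test_distant_protein_opens_new_family(self):
        refs = [LabeledProtein("ref", "WWWWWWWWWWWWWWWWWWWW", 5, "A")]
        (a,) = assign_families({"p": "KKKKKKKKKKKKKKKKKKKK"}, refs)
        assert a.family == 6  # 1 + max existing
        assert a.subfamily == "A"

    def test_midband_identity_opens_new_subfamily_letter(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(AA, 200))
        # ~50% substitutions -> identity in the 40-60 family band
        mutant = synthetic._mutate(rng, base, 0.45)
        ident = global_identity(base, mutant)
        assert 40 < ident <= 60
        refs = [LabeledProtein("ref", base, 2, "B")]
        (a,) = assign_families({"p": mutant}, refs)
        assert a.family == 2
        assert a.subfamily == "A"  # first unused letter in family 2

    def test_planted_partition_recovered_exactly(self):
        proteins, truth = synthetic.gen_protein_superfamily(3, 2, 2, seed=5)
        refs = [
            LabeledProtein(pid, proteins[pid], *truth.family_partition[pid])
            for pid in list(proteins)[:1]
        ]
        assignments = assign_families(proteins, refs)
        recovered = {a.protein_id: (a.family, a.subfamily) for a in assignments}
        # identical partition up to label names: compare co-membership
        planted = truth.family_partition
        ids = list(proteins)
        for i, x in enumerate(ids):
            for y in ids[i + 1 :]:
                assert (planted[x] == planted[y]) == (recovered[x] == recovered[y])

    def test_idempotent_on_own_output(self):
        proteins, truth = synthetic.gen_protein_superfamily(2, 2, 2, seed=9)
        refs = [LabeledProtein(pid, proteins[pid], *truth.family_partition[pid]) for pid in list(proteins)[:2]]
        first = assign_families(proteins, refs)
        as_refs = [LabeledProtein(a.protein_id, proteins[a.protein_id], a.family, a.subfamily) for a in first]
        second = assign_families(proteins, as_refs)
        assert [(a.protein_id, a.family, a.subfamily) for a in first] == [
            (a.protein_id, a.family, a.subfamily) for a in second
        ]

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValidationError):
            assign_families({"p": "ACDEF"}, [])


class TestNaming:
    def test_explicit_member_index_preserved(self):
        assert name_genes([FamilyAssignment("p", 3, "H", 2)], "Ca") == ["CaALDH3H2"]

    def test_dense_numbering_in_catalog_order(self):
        assignments = [
            FamilyAssignment("p1", 10, "A", 8),
            FamilyAssignment("p2", 10, "A", 9),
            FamilyAssignment("p3", 10, "A", None),
        ]
        # explicit 8 and 9 kept; the unindexed member fills from 1
        assert name_genes(assignments, "Ca") == ["CaALDH10A8", "CaALDH10A9", "CaALDH10A1"]

    def test_unindexed_members_number_from_one(self):
        assignments = [FamilyAssignment("p", 3, "F", None), FamilyAssignment("q", 3, "F", None)]
        assert name_genes(assignments, "") == ["ALDH3F1", "ALDH3F2"]

    def test_empty_input(self):
        assert name_genes([], "Ca") == []
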