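"""Cleavage-rule engine: cut sites, digestion, built-in specificities."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdigest import (
    CleavageRule,
    EnzymeSpec,
    ProteinRecord,
    builtin_enzyme,
    digest,
    find_cut_sites,
)
from pepdigest.errors import UnknownEnzymeError
from conftest import oracle_cut_sites, oracle_fragments, random_protein

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80)

TRYPSIN = builtin_enzyme("trypsin")
CHYMO = builtin_enzyme("chymotrypsin")
PEPSIN = builtin_enzyme("pepsin_ph1.3")


class TestFindCutSites:
    def test_trypsin_proline_veto(self):
        # K-P bond at position 2 is vetoed; K-A bond at 5 cuts
        assert find_cut_sites("AKPGKA", TRYPSIN) == [5]

    def test_chymotrypsin_aromatic_p1(self):
        assert find_cut_sites("GWGFG", CHYMO) == [2, 4]

    def test_pepsin_cuts_on_either_side_of_fl(self):
        # P1 rule fires after L (bond 2); P1' rule fires before L (bond 1)
        assert find_cut_sites("ALA", PEPSIN) == [1, 2]

    @pytest.mark.parametrize("enzyme", [TRYPSIN, CHYMO, PEPSIN])
    def test_matches_bond_by_bond_oracle_on_random_30mers(self, enzyme):
        rng = random.Random(42)
        for _ in range(200):
            seq = random_protein(rng, 30).sequence
            assert find_cut_sites(seq, enzyme) == oracle_cut_sites(seq, enzyme)


class TestDigest:
    def test_trypsin_toy_example(self):
        frags = digest(ProteinRecord(accession="t", sequence="AAKGGRCC"), [TRYPSIN])
        assert [(f.sequence, f.start, f.end) for f in frags] == [
            ("AAK", 1, 3),
            ("GGR", 4, 6),
            ("CC", 7, 8),
        ]

    def test_empty_enzyme_list_returns_intact_protein(self):
        protein = ProteinRecord(accession="t", sequence="MKWVTF")
        (frag,) = digest(protein, [])
        assert (frag.sequence, frag.start, frag.end) == ("MKWVTF", 1, 6)

    def test_fragment_sequences_match_parent_coordinates(self):
        protein = ProteinRecord(accession="t", sequence="AKPGKAFLYWRK")
        for frag in digest(protein, [TRYPSIN, CHYMO, PEPSIN]):
            assert protein.sequence[frag.start - 1 : frag.end] == frag.sequence

    def test_multiset_equals_brute_force_on_random_50mers(self, gi_enzymes):
        rng = random.Random(7)
        for _ in range(200):
            protein = random_protein(rng, 50)
            got = sorted(f.sequence for f in digest(protein, gi_enzymes))
            assert got == sorted(oracle_fragments(protein.sequence, gi_enzymes))

    def test_monotonicity_adding_enzyme_never_reduces_fragments(self):
        rng = random.Random(11)
        for _ in range(100):
            protein = random_protein(rng, 60)
            n1 = len(digest(protein, [TRYPSIN]))
            n2 = len(digest(protein, [TRYPSIN, CHYMO]))
            n3 = len(digest(protein, [TRYPSIN, CHYMO, PEPSIN]))
            assert n1 <= n2 <= n3

    def test_full_cleavage_fixpoint_for_p1_only_enzymes(self):
        """Re-digesting a released fragment with the same P1-side enzymes
        leaves it unchanged (full-cleavage idempotence)."""
        rng = random.Random(13)
        for _ in range(50):
            protein = random_protein(rng, 60)
            for frag in digest(protein, [TRYPSIN, CHYMO]):
                refrag = digest(
                    ProteinRecord(accession="f", sequence=frag.sequence),
                    [TRYPSIN, CHYMO],
                )
                assert [f.sequence for f in refrag] == [frag.sequence]

    def test_p1_prime_enzyme_refragmentation_agrees_with_oracle(self, gi_enzymes):
        """With a P1'-side pepsin rule the fixpoint does not hold at a
        fragment's first bond; assert agreement with the oracle instead."""
        rng = random.Random(17)
        for _ in range(50):
            protein = random_protein(rng, 60)
            for frag in digest(protein, gi_enzymes):
                refrag = digest(
                    ProteinRecord(accession="f", sequence=frag.sequence), gi_enzymes
                )
                assert [f.sequence for f in refrag] == oracle_fragments(
                    frag.sequence, gi_enzymes
                )


@settings(max_examples=100, derandomize=True)
@given(sequences)
def test_conservation_fragments_tile_parent(seq):
    """Fragments tile the parent exactly: no gaps, no overlaps, full cover."""
    protein = ProteinRecord(accession="p", sequence=seq)
    enzymes = [TRYPSIN, CHYMO, PEPSIN]
    frags = digest(protein, enzymes)
    assert "".join(f.sequence for f in frags) == seq
    expected_start = 1
    for frag in frags:
        assert frag.start == expected_start
        expected_start = frag.end + 1
    assert frags[-1].end == len(seq)


class TestRegistry:
    def test_trypsin_rule_contents(self):
        (rule,) = TRYPSIN.rules
        assert rule.p1 == frozenset("KR")
        assert rule.blocked_p1_prime == frozenset("P")
        assert TRYPSIN.ec_number == "3.4.21.4"

    def test_pepsin_has_p1_and_p1_prime_rules(self):
        p1_sets = [r.p1 for r in PEPSIN.rules]
        p1p_sets = [r.p1_prime for r in PEPSIN.rules]
        assert frozenset("FL") in p1_sets
        assert frozenset("FL") in p1p_sets

    def test_unknown_enzyme_lists_available(self):
        with pytest.raises(UnknownEnzymeError, match="trypsin"):
            builtin_enzyme("elastase")

    def test_rule_requires_a_constraint(self):
        with pytest.raises(ValueError):
            CleavageRule()

    def test_enzyme_requires_rules(self):
        with pytest.raises(ValueError):
            EnzymeSpec(name="x", ec_number="0.0.0.0", rules=())
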