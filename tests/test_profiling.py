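"""Profiling statistics A, B, A_E, W and their identities."""

import random

import pytest

from pepdigest import (
    ActivityDB,
    ActivityRecord,
    ProteinRecord,
    builtin_enzyme,
    count_occurrences,
    digest,
    parameter_A,
    parameter_AE,
    parameter_B,
    parameter_W,
    profile_protein,
)
from pepdigest.cleavage import PeptideFragment
from pepdigest.errors import ConsistencyError
from conftest import oracle_occurrences, random_protein

TRYPSIN = builtin_enzyme("trypsin")


def db_of(*pairs) -> ActivityDB:
    return ActivityDB(records=[ActivityRecord(sequence=s, activity_class=c, ec50=e, ec50_unit=u)
                               for s, c, e, u in pairs])


class TestCountOccurrences:
    def test_non_overlapping(self):
        assert count_occurrences("ILIL", "IL").positions == (1, 3)

    def test_overlapping_occurrences_counted(self):
        assert count_occurrences("AAAA", "AA").positions == (1, 2, 3)

    def test_absent_peptide(self):
        assert count_occurrences("ACDE", "KR").positions == ()

    def test_peptide_longer_than_parent_is_empty_hit(self):
        assert count_occurrences("AC", "ACDE").count == 0

    def test_matches_every_start_oracle(self):
        rng = random.Random(3)
        for _ in range(100):
            parent = random_protein(rng, 40).sequence
            peptide = parent[5:7]  # guaranteed at least one occurrence
            got = count_occurrences(parent, peptide)
            assert list(got.positions) == oracle_occurrences(parent, peptide)


class TestParameterA:
    def test_two_motifs(self):
        db = db_of(("IL", "c", None, "mM"), ("VL", "c", None, "mM"))
        prof = parameter_A(ProteinRecord(accession="p", sequence="ILVLAA"), db, "c")
        assert prof.A == pytest.approx(2 / 6)
        assert prof.N == 6

    def test_overlap_counted_in_frequency(self):
        db = db_of(("IL", "c", None, "mM"))
        prof = parameter_A(ProteinRecord(accession="p", sequence="ILIL"), db, "c")
        assert prof.A == pytest.approx(0.5)

    def test_empty_class_gives_zero(self):
        db = db_of(("IL", "c", None, "mM"))
        prof = parameter_A(ProteinRecord(accession="p", sequence="ILIL"), db, "other")
        assert prof.A == 0.0


class TestParameterB:
    def test_ec50_weighting(self):
        db = db_of(("KA", "c", 0.5, "mM"))
        protein = ProteinRecord(accession="p", sequence="AAKAAAAAAG")  # one KA, N=10
        prof = parameter_B(protein, db, "c")
        assert prof.b_defined
        assert prof.B == pytest.approx((1 / 0.5) / 10)

    def test_micromolar_unit_equivalent(self):
        db = db_of(("KA", "c", 500.0, "uM"))
        protein = ProteinRecord(accession="p", sequence="AAKAAAAAAG")
        assert parameter_B(protein, db, "c").B == pytest.approx(0.2)

    def test_zero_occurrences_gives_zero_B(self):
        db = db_of(("KA", "c", 0.5, "mM"))
        protein = ProteinRecord(accession="p", sequence="GGGGGGGGGG")
        prof = parameter_B(protein, db, "c")
        assert prof.b_defined and prof.B == 0.0

    def test_no_ec50_anywhere_leaves_B_undefined(self):
        db = db_of(("IL", "c", None, "mM"))
        prof = parameter_B(ProteinRecord(accession="p", sequence="ILIL"), db, "c")
        assert not prof.b_defined and prof.B is None
        assert prof.peptides_without_ec50 == 1


class TestParameterAE:
    def test_substring_is_not_a_release(self):
        db = db_of(("IL", "c", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="AAKILRCC")
        frags = digest(protein, [TRYPSIN])
        assert [f.sequence for f in frags] == ["AAK", "ILR", "CC"]
        ae = parameter_AE(protein, frags, db, "c")
        assert ae.A_E == 0.0  # IL occurs as a substring but is never released

    def test_released_fragments_counted_with_coordinates(self):
        db = db_of(("ILK", "c", None, "mM"), ("VLK", "c", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="ILKVLK")
        frags = digest(protein, [TRYPSIN])
        ae = parameter_AE(protein, frags, db, "c")
        assert ae.A_E == pytest.approx(2 / 6)
        assert [(f.sequence, f.coordinate_label()) for f in ae.released] == [
            ("ILK", "[1-3]"),
            ("VLK", "[4-6]"),
        ]

    def test_foreign_fragments_rejected(self):
        db = db_of(("IL", "c", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="ILKVLK")
        alien = [PeptideFragment(parent_accession="q", start=1, end=2, sequence="IL")]
        with pytest.raises(ConsistencyError):
            parameter_AE(protein, alien, db, "c")


class TestParameterW:
    def test_ratio(self):
        db = db_of(("ILK", "c", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="ILKILKAA")
        frags = digest(protein, [TRYPSIN])
        prof = parameter_A(protein, db, "c")
        ae = parameter_W(parameter_AE(protein, frags, db, "c"), prof)
        assert ae.w_defined
        assert ae.W == pytest.approx(1.0)  # both occurrences are released

    def test_zero_release_gives_zero_W(self):
        db = db_of(("IL", "c", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="AAKILRCC")
        prof = parameter_A(protein, db, "c")
        ae = parameter_W(parameter_AE(protein, digest(protein, [TRYPSIN]), db, "c"), prof)
        assert ae.w_defined and ae.W == 0.0

    def test_undefined_when_A_zero(self):
        db = db_of(("WW", "c", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="AAKAAK")
        prof = parameter_A(protein, db, "c")
        ae = parameter_W(parameter_AE(protein, digest(protein, [TRYPSIN]), db, "c"), prof)
        assert not ae.w_defined and ae.W is None

    def test_class_mismatch_rejected(self):
        db = db_of(("IL", "c", None, "mM"), ("IL", "d", None, "mM"))
        protein = ProteinRecord(accession="p", sequence="ILIL")
        prof = parameter_A(protein, db, "c")
        ae = parameter_AE(protein, digest(protein, [TRYPSIN]), db, "d")
        with pytest.raises(ConsistencyError):
            parameter_W(ae, prof)


class TestIdentities:
    def test_W_times_A_equals_AE_and_AE_at_most_A(self, activity_db, gi_enzymes):
        """On random proteins: W*A = A_E exactly and A_E <= A, for both
        packaged activity classes."""
        rng = random.Random(23)
        for _ in range(50):
            protein = random_protein(rng, 120)
            frags = digest(protein, gi_enzymes)
            for cls in activity_db.classes():
                prof, ae = profile_protein(protein, frags, activity_db, cls)
                assert ae.A_E <= prof.A + 1e-12
                if ae.w_defined:
                    assert ae.W * prof.A == pytest.approx(ae.A_E, abs=1e-12)
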