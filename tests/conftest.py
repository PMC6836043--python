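"""Shared fixtures and independent oracles.

The oracles here re-derive expected results by the most literal possible
method (scan every bond, scan every start position) and are kept free of
any call into the code paths they check.
"""

from __future__ import annotations

import random

import pytest

from pepdigest import (
    ActivityDB,
    ActivityRecord,
    ProteinRecord,
    builtin_enzyme,
    packaged_activity_db,
    packaged_physchem_entries,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_cut_sites(sequence: str, enzyme) -> list[int]:
    """Brute-force scan of every bond, applying the rule predicate directly."""
    cuts = []
    for i in range(1, len(sequence)):
        left, right = sequence[i - 1], sequence[i]
        for rule in enzyme.rules:
            if (
                (rule.p1 is None or left in rule.p1)
                and (rule.p1_prime is None or right in rule.p1_prime)
                and right not in rule.blocked_p1_prime
            ):
                cuts.append(i)
                break
    return cuts


def oracle_fragments(sequence: str, enzymes) -> list[str]:
    """Mark cuts for all enzymes, then split — the reference digest."""
    cut = set()
    for enzyme in enzymes:
        cut.update(oracle_cut_sites(sequence, enzyme))
    pieces, start = [], 0
    for i in sorted(cut):
        pieces.append(sequence[start:i])
        start = i
    pieces.append(sequence[start:])
    return pieces


def oracle_occurrences(parent: str, peptide: str) -> list[int]:
    """Check every start position for a match (1-based starts)."""
    return [
        s + 1
        for s in range(len(parent) - len(peptide) + 1)
        if parent[s : s + len(peptide)] == peptide
    ]


def random_protein(rng: random.Random, length: int, accession: str = "RND") -> ProteinRecord:
    return ProteinRecord(accession=accession, sequence="".join(rng.choices(AA, k=length)))


@pytest.fixture(scope="session")
def activity_db() -> ActivityDB:
    return packaged_activity_db()


@pytest.fixture(scope="session")
def table5_entries():
    return packaged_physchem_entries()


@pytest.fixture(scope="session")
def gi_enzymes():
    return [builtin_enzyme(n) for n in ("pepsin_ph1.3", "trypsin", "chymotrypsin")]


@pytest.fixture
def toy_db() -> ActivityDB:
    return ActivityDB(
        records=[
            ActivityRecord(sequence="IL", activity_class="gusp"),
            ActivityRecord(sequence="IL", activity_class="dpp4_inhibitor"),
            ActivityRecord(sequence="VL", activity_class="dpp4_inhibitor"),
            ActivityRecord(
                sequence="KA", activity_class="dpp4_inhibitor", ec50=6.27, ec50_unit="mM"
            ),
        ]
    )
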