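"""Bioactivity profiling statistics.

Four per-protein statistics quantify a protein as a precursor of
bioactive peptides of one activity class:

* A — frequency of bioactive fragments: total (overlap-counted)
  occurrences of the class's peptides in the protein, divided by the
  protein length N;
* B — receptor affinity in 1/mM: occurrences weighted by 1/EC50 (mM),
  divided by N (undefined when no class peptide carries an EC50);
* A_E — frequency of release: digest fragments (with multiplicity)
  whose sequence is in the class, divided by N;
* W — relative release frequency: A_E / A (undefined when A = 0).

The identities W*A = A_E and A_E <= A hold whenever defined: a peptide
cannot be released as a fragment more often than it occurs as a
substring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .activity import ActivityDB
from .cleavage import PeptideFragment
from .errors import ConsistencyError
from .sequence_io import ProteinRecord

#: Report rounding, per the tabular output conventions.
A_DECIMALS = 4
B_DECIMALS = 6


@dataclass(frozen=True)
class OccurrenceHit:
    """All (possibly overlapping) occurrences of one peptide in a parent."""

    peptide: str
    positions: tuple[int, ...]  # 1-based start indices, strictly increasing

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass
class ProfileResult:
    """Intact-protein profile for one activity class (statistics A and B)."""

    activity_class: str
    A: float
    N: int
    B: Optional[float] = None
    b_defined: bool = False
    peptides_without_ec50: int = 0


@dataclass
class DigestProfile:
    """Digest profile for one activity class (statistics A_E and W)."""

    activity_class: str
    A_E: float
    N: int
    released: list[PeptideFragment] = field(default_factory=list)
    W: Optional[float] = None
    w_defined: bool = False


def count_occurrences(parent: str, peptide: str) -> OccurrenceHit:
    """Left-to-right scan for every (overlapping) occurrence of ``peptide``.

    A peptide longer than the parent yields an empty hit, not an error.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    positions = []
    start = parent.find(peptide)
    while start != -1:
        positions.append(start + 1)
        start = parent.find(peptide, start + 1)
    return OccurrenceHit(peptide=peptide, positions=tuple(positions))


def parameter_A(protein: ProteinRecord, db: ActivityDB, activity_class: str) -> ProfileResult:
    """Frequency of bioactive fragments of ``activity_class`` in the protein."""
    peptides = db.peptides_for(activity_class)
    total = sum(count_occurrences(protein.sequence, p).count for p in peptides)
    return ProfileResult(activity_class=activity_class, A=total / len(protein), N=len(protein))


def parameter_B(protein: ProteinRecord, db: ActivityDB, activity_class: str) -> ProfileResult:
    """EC50-weighted potential activity of the protein, in 1/mM.

    Class peptides without an EC50 contribute nothing and are counted in
    ``peptides_without_ec50``; when no peptide carries an EC50 at all, B is
    undefined (``b_defined`` False, B None).
    """
    result = parameter_A(protein, db, activity_class)
    peptides = db.peptides_for(activity_class)
    weighted = 0.0
    n_with = 0
    n_without = 0
    for pep in peptides:
        ec50 = db.ec50_mM(pep, activity_class)
        if ec50 is None:
            n_without += 1
            continue
        n_with += 1
        hits = count_occurrences(protein.sequence, pep).count
        weighted += hits / ec50
    result.peptides_without_ec50 = n_without
    if n_with == 0:
        result.B = None
        result.b_defined = False
    else:
        result.B = weighted / len(protein)
        result.b_defined = True
    return result


def _check_fragments(protein: ProteinRecord, fragments: Sequence[PeptideFragment]) -> None:
    for frag in fragments:
        if frag.parent_accession != protein.accession:
            raise ConsistencyError(
                f"fragment {frag.sequence!r} belongs to {frag.parent_accession!r}, "
                f"not {protein.accession!r}"
            )
        if protein.sequence[frag.start - 1 : frag.end] != frag.sequence:
            raise ConsistencyError(
                f"fragment {frag.sequence!r} does not match parent "
                f"{protein.accession!r} at [{frag.start}-{frag.end}]"
            )


def parameter_AE(
    protein: ProteinRecord,
    fragments: Sequence[PeptideFragment],
    db: ActivityDB,
    activity_class: str,
) -> DigestProfile:
    """Frequency of release of class peptides by the digest.

    Only whole released fragments count (a class peptide that survives
    merely as a substring of a longer fragment does not); fragments are
    counted with multiplicity.
    """
    _check_fragments(protein, fragments)
    members = db.peptides_for(activity_class)
    released = [f for f in fragments if f.sequence in members]
    return DigestProfile(
        activity_class=activity_class,
        A_E=len(released) / len(protein),
        N=len(protein),
        released=released,
    )


def parameter_W(ae: DigestProfile, profile: ProfileResult) -> DigestProfile:
    """Relative release frequency W = A_E / A (undefined when A = 0).

    Fills ``W``/``w_defined`` on the digest profile in place and returns it.
    """
    if ae.activity_class != profile.activity_class:
        raise ConsistencyError(
            f"activity class mismatch: {ae.activity_class!r} vs {profile.activity_class!r}"
        )
    if ae.N != profile.N:
        raise ConsistencyError(f"protein length mismatch: {ae.N} vs {profile.N}")
    if profile.A > 0:
        ae.W = ae.A_E / profile.A
        ae.w_defined = True
    else:
        ae.W = None
        ae.w_defined = False
    return ae


def profile_protein(
    protein: ProteinRecord,
    fragments: Sequence[PeptideFragment],
    db: ActivityDB,
    activity_class: str,
) -> tuple[ProfileResult, DigestProfile]:
    """Convenience: compute A, B, A_E and W for one protein and class."""
    profile = parameter_B(protein, db, activity_class)
    ae = parameter_AE(protein, fragments, db, activity_class)
    parameter_W(ae, profile)
    return profile, ae
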