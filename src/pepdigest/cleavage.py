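"""Protease cleavage-rule engine and in silico digestion.

A protease is described declaratively by one or more
:class:`CleavageRule` objects over the P1/P1' positions of a peptide bond
(P1 = residue immediately N-terminal of the scissile bond, P1' = residue
immediately C-terminal).  Digestion is full cleavage by all enzymes acting
simultaneously: the cut-site set is the union over enzymes, and fragments
are the maximal substrings between consecutive cuts, with 1-based inclusive
coordinates in the parent protein.

Built-in specificities follow the conventions of the common cleavage
predictors: trypsin after K/R not before P; chymotrypsin after F/Y/W not
before P; pepsin (pH 1.3) at bonds with F or L on either side of the bond.
All of them are plain data, so alternative dialects can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence

from .errors import UnknownEnzymeError
from .sequence_io import AMINO_ACIDS, ProteinRecord, validate_sequence


@dataclass(frozen=True)
class CleavageRule:
    """One cut rule: ``None`` for p1/p1_prime means wildcard (any residue).

    A bond cuts under this rule iff the P1 residue is in ``p1`` (or p1 is
    wildcard), the P1' residue is in ``p1_prime`` (or wildcard), and the
    P1' residue is not in ``blocked_p1_prime``.
    """

    p1: Optional[FrozenSet[str]] = None
    p1_prime: Optional[FrozenSet[str]] = None
    blocked_p1_prime: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.p1 is None and self.p1_prime is None:
            raise ValueError("at least one of p1/p1_prime must be constrained")
        for name in ("p1", "p1_prime", "blocked_p1_prime"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, frozenset(value))
                if not frozenset(value) <= AMINO_ACIDS:
                    raise ValueError(f"{name} contains non-standard residues: {value}")
        if self.p1_prime is not None and self.p1_prime & self.blocked_p1_prime:
            raise ValueError("p1_prime and blocked_p1_prime must be disjoint")

    def fires(self, left: str, right: str) -> bool:
        """Does this rule cut the bond between residues ``left`` and ``right``?"""
        if self.p1 is not None and left not in self.p1:
            return False
        if self.p1_prime is not None and right not in self.p1_prime:
            return False
        return right not in self.blocked_p1_prime


@dataclass(frozen=True)
class EnzymeSpec:
    """A named protease with an ordered list of cleavage rules."""

    name: str
    ec_number: str
    rules: tuple[CleavageRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"enzyme {self.name!r} needs at least one rule")
        object.__setattr__(self, "rules", tuple(self.rules))


@dataclass(frozen=True)
class PeptideFragment:
    """A released peptide located in its parent (1-based inclusive coords,
    the ``[start-end]`` bracket convention of released-fragment tables)."""

    parent_accession: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad fragment coordinates [{self.start}-{self.end}]")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates [{self.start}-{self.end}] do not match "
                f"sequence length {len(self.sequence)}"
            )

    def coordinate_label(self) -> str:
        """Human-readable ``[start-end]`` label."""
        return f"[{self.start}-{self.end}]"


def find_cut_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Bond indices cut by ``enzyme`` in ``sequence``, sorted ascending.

    Bond index ``i`` (1-based, ``1 <= i <= len-1``) denotes the bond between
    residues ``i`` and ``i+1``.  A bond is cut iff any rule fires.
    """
    validate_sequence(sequence)
    cuts = []
    for i in range(1, len(sequence)):
        left, right = sequence[i - 1], sequence[i]
        if any(rule.fires(left, right) for rule in enzyme.rules):
            cuts.append(i)
    return cuts


def digest(protein: ProteinRecord, enzymes: Sequence[EnzymeSpec]) -> list[PeptideFragment]:
    """Full simultaneous digestion: fragments between the union of cut sites.

    With an empty enzyme list the intact protein is returned as a single
    fragment.  Fragments tile the parent exactly (no gaps, no overlaps) in
    N-to-C order.
    """
    cut_set: set[int] = set()
    for enzyme in enzymes:
        cut_set.update(find_cut_sites(protein.sequence, enzyme))
    boundaries = [0] + sorted(cut_set) + [len(protein.sequence)]
    fragments = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        fragments.append(
            PeptideFragment(
                parent_accession=protein.accession,
                start=lo + 1,
                end=hi,
                sequence=protein.sequence[lo:hi],
            )
        )
    return fragments


_REGISTRY: dict[str, EnzymeSpec] = {
    "trypsin": EnzymeSpec(
        name="trypsin",
        ec_number="3.4.21.4",
        rules=(CleavageRule(p1=frozenset("KR"), blocked_p1_prime=frozenset("P")),),
    ),
    "chymotrypsin": EnzymeSpec(
        name="chymotrypsin",
        ec_number="3.4.21.1",
        rules=(CleavageRule(p1=frozenset("FYW"), blocked_p1_prime=frozenset("P")),),
    ),
    # Gastric pepsin at stomach pH: cuts bonds with Phe/Leu at P1 or P1'.
    "pepsin_ph1.3": EnzymeSpec(
        name="pepsin_ph1.3",
        ec_number="3.4.23.1",
        rules=(
            CleavageRule(p1=frozenset("FL")),
            CleavageRule(p1_prime=frozenset("FL")),
        ),
    ),
    # Broader specificity above pH 2 (adds the other aromatics).
    "pepsin_ph_gt2": EnzymeSpec(
        name="pepsin_ph_gt2",
        ec_number="3.4.23.1",
        rules=(
            CleavageRule(p1=frozenset("FLWY")),
            CleavageRule(p1_prime=frozenset("FLWY")),
        ),
    ),
}

#: The gastrointestinal enzyme set used for the digestion simulations.
GASTROINTESTINAL_ENZYMES = ("pepsin_ph1.3", "trypsin", "chymotrypsin")


def available_enzymes() -> list[str]:
    return sorted(_REGISTRY)


def builtin_enzyme(name: str) -> EnzymeSpec:
    """Look up a built-in protease by name.

    Raises :class:`~pepdigest.errors.UnknownEnzymeError` listing the
    available names for an unknown enzyme.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownEnzymeError(
            f"unknown enzyme {name!r}; available: {', '.join(available_enzymes())}"
        ) from None


def resolve_enzymes(names: Iterable[str]) -> list[EnzymeSpec]:
    """Resolve a list of enzyme names against the registry."""
    return [builtin_enzyme(name) for name in names]
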