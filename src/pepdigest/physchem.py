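"""Peptide physico-chemical properties.

Molecular weight is the sum of average residue masses plus one water;
net charge at a given pH is the Henderson-Hasselbalch sum over ionizable
groups (N-terminus, His, Lys, Arg positive; C-terminus, Asp, Glu, Cys,
Tyr negative); the isoelectric point is the unique pH where the net
charge crosses zero, found by bisection (the charge is strictly
decreasing in pH, so the root is unique).  Solubility in water is a
coarse flag: good iff the peptide carries at least one charged residue
(D, E, K or R).

The default mass and pKa tables are packaged CSV resources; alternative
named tables (e.g. the EMBOSS set) can be selected, and fully custom
tables supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import resources
from .errors import MissingScoreError
from .sequence_io import AMINO_ACIDS, PeptideEntry, validate_sequence

#: Side chains treated as bases / acids in the charge model.
BASIC_SIDE_CHAINS = frozenset("HKR")
ACIDIC_SIDE_CHAINS = frozenset("DECY")

WATER_MASS = 18.0153  # g/mol, average


@dataclass(frozen=True)
class MassTable:
    """Average residue masses in g/mol (monoisotopic variant optional)."""

    residue_mass: Mapping[str, float]
    water_mass: float = WATER_MASS
    monoisotopic_mass: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - set(self.residue_mass)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_mass.values()):
            raise ValueError("residue masses must be positive")


@dataclass(frozen=True)
class PKaSet:
    """Named pKa set: termini plus the seven ionizable side chains."""

    name: str
    n_term: float
    c_term: float
    side_chain: Mapping[str, float]  # keys among D, E, H, C, Y, K, R

    def __post_init__(self) -> None:
        values = [self.n_term, self.c_term, *self.side_chain.values()]
        if any(not (0.0 < v < 14.0) for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")


def load_mass_table(name: str = "default") -> MassTable:
    """Load a packaged mass table by name (``default`` or ``emboss``)."""
    df = resources.load_mass_table_frame(name)
    return MassTable(
        residue_mass=dict(zip(df["residue"], df["average_mass"].astype(float))),
        monoisotopic_mass=dict(zip(df["residue"], df["monoisotopic_mass"].astype(float))),
    )


def load_pka_set(name: str = "classic") -> PKaSet:
    """Load a packaged pKa set by name (``classic`` or ``emboss``)."""
    df = resources.load_pka_frame(name)
    table = dict(zip(df["group"], df["pka"].astype(float)))
    return PKaSet(
        name=name,
        n_term=table.pop("n_term"),
        c_term=table.pop("c_term"),
        side_chain=table,
    )


_DEFAULT_MASSES: Optional[MassTable] = None
_DEFAULT_PKAS: Optional[PKaSet] = None


def default_mass_table() -> MassTable:
    global _DEFAULT_MASSES
    if _DEFAULT_MASSES is None:
        _DEFAULT_MASSES = load_mass_table("default")
    return _DEFAULT_MASSES


def default_pka_set() -> PKaSet:
    global _DEFAULT_PKAS
    if _DEFAULT_PKAS is None:
        _DEFAULT_PKAS = load_pka_set("classic")
    return _DEFAULT_PKAS


def molecular_weight(sequence: str, masses: Optional[MassTable] = None) -> float:
    """Average molecular weight in g/mol (full precision, not rounded)."""
    masses = masses or default_mass_table()
    validate_sequence(sequence)
    return sum(masses.residue_mass[aa] for aa in sequence) + masses.water_mass


def net_charge(sequence: str, ph: float = 7.0, pkas: Optional[PKaSet] = None) -> float:
    """Net charge at ``ph`` by the Henderson-Hasselbalch equation.

    Positive groups contribute ``1/(1+10^(pH-pKa))``, negative groups
    ``-1/(1+10^(pKa-pH))``.
    """
    pkas = pkas or default_pka_set()
    validate_sequence(sequence)
    positive = 1.0 / (1.0 + 10.0 ** (ph - pkas.n_term))
    negative = 1.0 / (1.0 + 10.0 ** (pkas.c_term - ph))
    for aa in sequence:
        if aa in BASIC_SIDE_CHAINS and aa in pkas.side_chain:
            positive += 1.0 / (1.0 + 10.0 ** (ph - pkas.side_chain[aa]))
        elif aa in ACIDIC_SIDE_CHAINS and aa in pkas.side_chain:
            negative += 1.0 / (1.0 + 10.0 ** (pkas.side_chain[aa] - ph))
    return positive - negative


def isoelectric_point(
    sequence: str,
    pkas: Optional[PKaSet] = None,
    tolerance: float = 1e-4,
) -> float:
    """The pH in (0, 14) where the net charge is zero, by bisection.

    Iterates until ``|charge| < tolerance`` and the bracket is narrower
    than 1e-6 pH units (the charge slope can be shallow between well
    separated pKas, so the charge criterion alone would leave the pH
    imprecise).  The charge is strictly decreasing in pH, so the root is
    unique for any valid sequence (both termini are always ionizable).
    """
    pkas = pkas or default_pka_set()
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        charge = net_charge(sequence, mid, pkas)
        if abs(charge) < tolerance and hi - lo < 1e-6:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return mid


def solubility_flag(sequence: str) -> bool:
    """Good water solubility iff at least one charged residue (D/E/K/R)."""
    validate_sequence(sequence)
    return any(aa in "DEKR" for aa in sequence)


@dataclass
class PhyschemRecord:
    """Reported properties for one peptide (report-precision rounding:
    MW 2 dp, pI 2 dp, charge 1 dp)."""

    sequence: str
    mw: float
    pi: float
    net_charge_ph: float
    soluble: bool
    bioactivity_score: Optional[float] = None

    @property
    def solubility_label(self) -> str:
        return "+" if self.soluble else "-"


def physchem_report(
    peptides: Sequence[PeptideEntry],
    masses: Optional[MassTable] = None,
    pkas: Optional[PKaSet] = None,
    ph: float = 7.0,
    score_key: str = "bioactivity_score",
) -> list[PhyschemRecord]:
    """One :class:`PhyschemRecord` per peptide, in input order.

    External bioactivity-score annotations (key ``score_key``) are passed
    through unchanged; all other columns are recomputed.
    """
    masses = masses or default_mass_table()
    pkas = pkas or default_pka_set()
    records = []
    for pep in peptides:
        score = pep.annotations.get(score_key)
        records.append(
            PhyschemRecord(
                sequence=pep.sequence,
                mw=round(molecular_weight(pep.sequence, masses), 2),
                pi=round(isoelectric_point(pep.sequence, pkas), 2),
                # +0.0 normalises -0.0 from rounding tiny negative charges
                net_charge_ph=round(net_charge(pep.sequence, ph, pkas), 1) + 0.0,
                soluble=solubility_flag(pep.sequence),
                bioactivity_score=float(score) if score is not None else None,
            )
        )
    return records


def report_dataframe(records: Sequence[PhyschemRecord]) -> pd.DataFrame:
    """Tabular view of a physico-chemical report (reference-table layout)."""
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "molecular_weight": [r.mw for r in records],
            "isoelectric_point": [r.pi for r in records],
            "net_charge": [r.net_charge_ph for r in records],
            "solubility": [r.solubility_label for r in records],
            "bioactivity_score": [r.bioactivity_score for r in records],
        }
    )
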