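"""Aggregate statistics and ranking over released peptides.

Pooled amino-acid composition, mean +/- sample SD, Pearson correlation
between physico-chemical columns, score-threshold candidate selection,
and the peptide-length distribution (dipeptide share).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import MissingScoreError, UndefinedStatisticError
from .physchem import PhyschemRecord


@dataclass
class CompositionTable:
    """Pooled residue counts and percentage shares over a peptide set."""

    counts: Mapping[str, int]
    total_residues: int

    @property
    def percent(self) -> dict[str, float]:
        """Percentage share per residue, rounded to 2 decimals."""
        return {
            aa: round(100.0 * n / self.total_residues, 2)
            for aa, n in sorted(self.counts.items())
        }


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    n: int


@dataclass(frozen=True)
class LengthBin:
    count: int
    fraction: float  # exact fraction, kept at full precision

    @property
    def percent(self) -> int:
        """Integer percentage for reports."""
        return round(100.0 * self.fraction)


def aa_composition(peptides: Sequence[str]) -> CompositionTable:
    """Amino-acid composition pooled over all residues of all sequences."""
    if not peptides:
        raise UndefinedStatisticError("composition of an empty peptide list")
    counts = Counter()
    for seq in peptides:
        counts.update(seq)
    return CompositionTable(counts=dict(counts), total_residues=sum(counts.values()))


def mean_sd(values: Sequence[float], sample: bool = True) -> tuple[float, float]:
    """Arithmetic mean and standard deviation (n-1 denominator by default)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UndefinedStatisticError("standard deviation needs at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1 if sample else 0))


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    variable_x: str = "x",
    variable_y: str = "y",
) -> CorrelationResult:
    """Product-moment correlation between two equal-length samples (n >= 3)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise UndefinedStatisticError("x and y must have equal length")
    if xa.size < 3:
        raise UndefinedStatisticError("correlation needs at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r = _scipy_stats.pearsonr(xa, ya).statistic
    return CorrelationResult(variable_x=variable_x, variable_y=variable_y, r=float(r), n=int(xa.size))


def select_by_score(
    records: Sequence[PhyschemRecord], threshold: float
) -> list[PhyschemRecord]:
    """Records with bioactivity score >= threshold (inclusive), sorted by
    descending score then sequence.

    The inclusive rule is deliberate: published candidate lists built
    "above" a cutoff in practice include peptides sitting exactly on it.
    """
    for rec in records:
        if rec.bioactivity_score is None:
            raise MissingScoreError(
                f"record {rec.sequence!r} lacks a bioactivity score"
            )
    selected = [r for r in records if r.bioactivity_score >= threshold]
    return sorted(selected, key=lambda r: (-r.bioactivity_score, r.sequence))


def length_distribution(peptides: Sequence[str]) -> dict[int, LengthBin]:
    """Peptide-length histogram with exact fractions (percent for reports)."""
    if not peptides:
        raise UndefinedStatisticError("length distribution of an empty list")
    counts = Counter(len(p) for p in peptides)
    n = len(peptides)
    return {
        length: LengthBin(count=c, fraction=c / n) for length, c in sorted(counts.items())
    }
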