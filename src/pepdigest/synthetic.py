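"""Synthetic proteins with planted bioactive motifs and known ground truth.

The generator emulates the study design — a panel of muscle-protein-sized
sequences screened for short bioactive motifs — with full control of the
truth: background residues are drawn i.i.d. from configurable
frequencies, motifs are planted at non-overlapping random positions, and
(optionally) each motif is flanked so that a trypsin digest releases it
exactly.  Ground truth is established *post hoc* by exhaustive scanning
of the emitted sequence (so accidental background matches are included)
and by an independent brute-force digest, never by planting bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cleavage import EnzymeSpec, builtin_enzyme
from .errors import PlacementError
from .sequence_io import Fraction, ProteinRecord

_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic study.

    Defaults mirror the scale of the original screen: a panel of 16
    proteins of a few hundred residues with uniform background.  A motif
    triple is ``(sequence, count, activity_class)``; with
    ``flank_released`` each planted motif is embedded as ``K + motif +
    X`` (X a non-Pro background residue) so a tryptic digest releases the
    motif exactly, which requires the motif to be trypsin-releasable
    (ends in K/R, does not start with P, no internal cleavable bond).
    """

    seed: int
    n_proteins: int = 16
    length: int = 300
    background_frequencies: Optional[Mapping[str, float]] = None
    planted_motifs: tuple[tuple[str, int, str], ...] = ()
    flank_released: bool = False
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.length < 1:
            raise ValueError("n_proteins and length must be positive")
        if self.background_frequencies is not None:
            probs = np.array(
                [self.background_frequencies.get(aa, 0.0) for aa in _ALPHABET]
            )
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")
        budget = sum(count * (len(m) + 2) for m, count, _ in self.planted_motifs)
        if budget > self.length:
            raise ValueError(
                f"planted motifs need {budget} residues but length is {self.length}"
            )


@dataclass
class ProteinTruth:
    """Per-protein ground truth, recounted from the emitted sequence."""

    occurrences: dict[str, int] = field(default_factory=dict)  # class -> substring count
    expected_A: dict[str, float] = field(default_factory=dict)
    released: dict[str, int] = field(default_factory=dict)  # class -> released fragments
    expected_AE: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Ground truth for a synthetic study, keyed by protein accession."""

    per_protein: dict[str, ProteinTruth] = field(default_factory=dict)
    motif_classes: dict[str, set[str]] = field(default_factory=dict)  # class -> motifs


def _is_trypsin_releasable(motif: str) -> bool:
    if motif[0] == "P" or motif[-1] not in "KR":
        return False
    # no internal cut: K/R inside the motif followed by a non-Pro residue
    # (every bond in this scan is internal; the bond after the last residue
    # is the release site itself)
    for left, right in zip(motif[:-1], motif[1:]):
        if left in "KR" and right != "P":
            return False
    return True


def _brute_force_fragments(sequence: str, enzymes: Sequence[EnzymeSpec]) -> list[str]:
    """Reference digest used only for ground truth: mark every cut bond by
    direct rule evaluation, then split."""
    cut = [False] * len(sequence)
    for enzyme in enzymes:
        for i in range(1, len(sequence)):
            left, right = sequence[i - 1], sequence[i]
            for rule in enzyme.rules:
                ok = (rule.p1 is None or left in rule.p1) and (
                    rule.p1_prime is None or right in rule.p1_prime
                ) and right not in rule.blocked_p1_prime
                if ok:
                    cut[i] = True
    fragments, start = [], 0
    for i in range(1, len(sequence)):
        if cut[i]:
            fragments.append(sequence[start:i])
            start = i
    fragments.append(sequence[start:])
    return fragments


def _count_all(parent: str, motif: str) -> int:
    """Exhaustive overlapping-occurrence scan over every start position."""
    return sum(1 for s in range(len(parent) - len(motif) + 1) if parent[s : s + len(motif)] == motif)


def generate_study(
    spec: SyntheticSpec,
    enzymes: Optional[Sequence[EnzymeSpec]] = None,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate the synthetic protein panel and its ground truth.

    ``enzymes`` (default: trypsin alone) defines the digest used for the
    release ground truth.  The same seed always yields byte-identical
    output; all randomness flows from one explicit RNG stream.
    """
    rng = np.random.default_rng(spec.seed)
    if enzymes is None:
        enzymes = [builtin_enzyme("trypsin")]
    if spec.background_frequencies is None:
        probs = np.full(len(_ALPHABET), 1.0 / len(_ALPHABET))
    else:
        probs = np.array([spec.background_frequencies.get(aa, 0.0) for aa in _ALPHABET])
        probs = probs / probs.sum()
    non_pro = [aa for aa, p in zip(_ALPHABET, probs) if p > 0 and aa != "P"]
    if spec.flank_released:
        for motif, count, _cls in spec.planted_motifs:
            if count and not _is_trypsin_releasable(motif):
                raise PlacementError(
                    f"motif {motif!r} is not trypsin-releasable (must end in K/R, "
                    "not start with P, and contain no internal cleavable bond)"
                )
        if not non_pro:
            raise PlacementError("background excludes every non-Pro residue")

    motif_classes: dict[str, set[str]] = {}
    for motif, _count, cls in spec.planted_motifs:
        motif_classes.setdefault(cls, set()).add(motif)

    proteins: list[ProteinRecord] = []
    truth = GroundTruth(motif_classes=motif_classes)

    for idx in range(spec.n_proteins):
        residues = list(rng.choice(_ALPHABET, size=spec.length, p=probs))
        # build insert blocks, then place them at non-overlapping positions
        blocks: list[str] = []
        for motif, count, _cls in spec.planted_motifs:
            for _ in range(count):
                if spec.flank_released:
                    tail = str(rng.choice(non_pro))
                    blocks.append("K" + motif + tail)
                else:
                    blocks.append(motif)
        occupied: list[tuple[int, int]] = []
        for block in blocks:
            placed = False
            for _ in range(spec.max_retries):
                start = int(rng.integers(0, spec.length - len(block) + 1))
                span = (start, start + len(block))
                if all(span[1] <= lo or span[0] >= hi for lo, hi in occupied):
                    occupied.append(span)
                    residues[span[0] : span[1]] = list(block)
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place motif block {block!r} after "
                    f"{spec.max_retries} retries (length {spec.length})"
                )
        sequence = "".join(residues)
        accession = f"SYN{idx:03d}"
        proteins.append(
            ProteinRecord(
                accession=accession,
                sequence=sequence,
                name=f"synthetic protein {idx}",
                fraction=Fraction.UNSPECIFIED,
            )
        )
        # ground truth by exhaustive post-hoc scan (accidental matches count)
        ptruth = ProteinTruth()
        released_seqs = _brute_force_fragments(sequence, enzymes)
        for cls, motifs in motif_classes.items():
            occ = sum(_count_all(sequence, m) for m in motifs)
            rel = sum(1 for f in released_seqs if f in motifs)
            ptruth.occurrences[cls] = occ
            ptruth.expected_A[cls] = occ / spec.length
            ptruth.released[cls] = rel
            ptruth.expected_AE[cls] = rel / spec.length
        truth.per_protein[accession] = ptruth

    return proteins, truth
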