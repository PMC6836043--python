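"""Peptide-to-bioactivity reference database.

All profiling statistics are computed against an :class:`ActivityDB`: a
set of short peptide sequences per activity class, optionally with an
EC50 (half-maximal effective concentration).  The packaged fixture holds
the 54 gastrointestinally released DPP-IV-inhibitory sequences plus the
two glucose-uptake-stimulating dipeptides (IL, VL), which are
multifunctional — every GUSP sequence is also a DPP-IV inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import pandas as pd

from .errors import DuplicateRecordError, SchemaError, SequenceValidationError, TableParseError
from .sequence_io import validate_sequence

#: Activity classes with a dedicated meaning; other labels are carried as-is.
DPP4_INHIBITOR = "dpp4_inhibitor"
GUSP = "gusp"

_EC50_TO_MM = {"mM": 1.0, "uM": 1e-3, "µM": 1e-3, "nM": 1e-6}


@dataclass(frozen=True)
class ActivityRecord:
    """One peptide with one activity class and an optional EC50."""

    sequence: str
    activity_class: str
    ec50: Optional[float] = None
    ec50_unit: str = "mM"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        validate_sequence(self.sequence, record=self.sequence)
        if self.ec50 is not None:
            if self.ec50 <= 0:
                raise SequenceValidationError(
                    f"EC50 must be positive, got {self.ec50} for {self.sequence!r}"
                )
            if self.ec50_unit not in _EC50_TO_MM:
                raise SequenceValidationError(
                    f"unknown EC50 unit {self.ec50_unit!r} for {self.sequence!r}"
                )

    @property
    def ec50_mM(self) -> Optional[float]:
        """EC50 converted to mM (the unit of the affinity statistic)."""
        if self.ec50 is None:
            return None
        return self.ec50 * _EC50_TO_MM[self.ec50_unit]


@dataclass
class ActivityDB:
    """Indexed collection of :class:`ActivityRecord`.

    Sequence lookup is case-insensitive (sequences are stored uppercase).
    A peptide may appear under several classes (multifunctionality).
    """

    records: list[ActivityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        self._index: dict[str, set[str]] = {}
        self._ec50: dict[tuple[str, str], Optional[float]] = {}
        for rec in self.records:
            key = (rec.sequence, rec.activity_class)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for sequence {rec.sequence!r}, "
                    f"class {rec.activity_class!r}"
                )
            seen.add(key)
            self._index.setdefault(rec.activity_class, set()).add(rec.sequence)
            self._ec50[key] = rec.ec50_mM

    def classes(self) -> list[str]:
        return sorted(self._index)

    def peptides_for(self, activity_class: str) -> set[str]:
        """The exact member set of a class (empty set if absent)."""
        return set(self._index.get(activity_class, set()))

    def ec50_mM(self, sequence: str, activity_class: str) -> Optional[float]:
        """EC50 in mM for a (sequence, class) pair, or None if not recorded."""
        return self._ec50.get((sequence.upper(), activity_class))

    def __len__(self) -> int:
        return len(self.records)


def load_activity_db(source: Union[str, Path, TextIO]) -> ActivityDB:
    """Load an activity table (CSV with header
    ``sequence,activity_class[,ec50,ec50_unit,source]``) into an ActivityDB."""
    sep = "\t" if isinstance(source, (str, Path)) and str(source).lower().endswith(
        (".tsv", ".tab")
    ) else ","
    df = pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True)
    for col in ("sequence", "activity_class"):
        if col not in df.columns:
            raise SchemaError(f"activity table requires a {col!r} column")
    records = []
    for row_idx, row in df.iterrows():
        ec50 = None
        raw = row.get("ec50")
        if raw is not None and not pd.isna(raw) and str(raw).strip():
            try:
                ec50 = float(str(raw).replace("−", "-"))
            except ValueError as exc:
                raise TableParseError(
                    f"non-numeric EC50 {raw!r} at row {row_idx}", row=int(row_idx)
                ) from exc
        unit = row.get("ec50_unit")
        unit = str(unit).strip() if unit is not None and not pd.isna(unit) and str(unit).strip() else "mM"
        source_txt = row.get("source")
        source_txt = str(source_txt) if source_txt is not None and not pd.isna(source_txt) else ""
        records.append(
            ActivityRecord(
                sequence=str(row["sequence"]).strip().upper(),
                activity_class=str(row["activity_class"]).strip(),
                ec50=ec50,
                ec50_unit=unit,
                source=source_txt,
            )
        )
    return ActivityDB(records=records)


def merge(*dbs: ActivityDB) -> ActivityDB:
    """Merge several databases (duplicate (sequence, class) pairs raise)."""
    records: list[ActivityRecord] = []
    for db in dbs:
        records.extend(db.records)
    return ActivityDB(records=records)
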