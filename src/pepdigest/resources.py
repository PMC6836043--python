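"""Accessors for the packaged reference data.

Everything lives as small CSV files under ``pepdigest/data``:

* ``table4_activity.csv`` — the released-peptide activity reference
  (54 DPP-IV inhibitors, 2 glucose-uptake stimulators);
* ``literature_ec50.csv`` — literature EC50 rows (KA, AAATP) for
  exercising the affinity statistic;
* ``table5_physchem.csv`` — the printed physico-chemical reference table
  (molecular weight, pI, net charge, solubility, external bioactivity
  score) for the 54 released peptides;
* mass tables and pKa sets, selectable by name.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .activity import ActivityDB, load_activity_db
from .sequence_io import PeptideEntry, load_peptide_table

_PKG = "pepdigest.data"


def _path(filename: str):
    return resources.files(_PKG).joinpath(filename)


def packaged_activity_db() -> ActivityDB:
    """The released-peptide activity reference shipped with the package."""
    with resources.as_file(_path("table4_activity.csv")) as p:
        return load_activity_db(p)


def literature_ec50_db() -> ActivityDB:
    """Literature DPP-IV inhibitors with measured EC50s (KA, AAATP)."""
    with resources.as_file(_path("literature_ec50.csv")) as p:
        return load_activity_db(p)


def packaged_physchem_table() -> pd.DataFrame:
    """The printed physico-chemical reference table as a DataFrame."""
    with resources.as_file(_path("table5_physchem.csv")) as p:
        return pd.read_csv(p)


def packaged_physchem_entries() -> list[PeptideEntry]:
    """The same table as :class:`~pepdigest.sequence_io.PeptideEntry` rows."""
    with resources.as_file(_path("table5_physchem.csv")) as p:
        return load_peptide_table(
            p,
            numeric_columns=(
                "molecular_weight",
                "isoelectric_point",
                "net_charge",
                "bioactivity_score",
            ),
        )


def available_mass_tables() -> list[str]:
    return ["default", "emboss"]


def load_mass_table_frame(name: str = "default") -> pd.DataFrame:
    if name not in available_mass_tables():
        raise KeyError(f"unknown mass table {name!r}; available: {available_mass_tables()}")
    with resources.as_file(_path(f"masses_{name}.csv")) as p:
        return pd.read_csv(p)


def available_pka_sets() -> list[str]:
    return ["classic", "emboss"]


def load_pka_frame(name: str = "classic") -> pd.DataFrame:
    if name not in available_pka_sets():
        raise KeyError(f"unknown pKa set {name!r}; available: {available_pka_sets()}")
    with resources.as_file(_path(f"pka_{name}.csv")) as p:
        return pd.read_csv(p)
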