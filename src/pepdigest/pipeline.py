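"""End-to-end orchestration: digest -> profile -> physchem -> report.

:class:`RunConfig` collects every knob of a run (inputs, enzyme names,
pKa/mass table names, pH, score threshold, output directory) and can be
loaded from YAML with flag-style overrides.  :func:`run_pipeline`
executes the stages, writes CSV tables plus a human-readable summary,
and removes partial outputs if a stage fails.  :func:`reproduce_reference`
recomputes every desk-checkable number of the published released-peptide
tables from the packaged fixtures.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import resources
from .activity import ActivityDB, load_activity_db
from .cleavage import GASTROINTESTINAL_ENZYMES, digest, resolve_enzymes
from .errors import PepdigestError
from .physchem import load_mass_table, load_pka_set, physchem_report, report_dataframe
from .profiling import A_DECIMALS, B_DECIMALS, profile_protein
from .sequence_io import PeptideEntry, load_peptide_table, parse_fasta, write_table
from .stats_report import (
    aa_composition,
    length_distribution,
    mean_sd,
    pearson,
    select_by_score,
)

logger = logging.getLogger("pepdigest")


class StageError(PepdigestError):
    """A pipeline stage failed (carries the stage name)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    fasta: Optional[str] = None
    activity_db: Optional[str] = None  # None -> packaged reference
    scores: Optional[str] = None  # optional peptide,bioactivity_score CSV
    enzymes: tuple[str, ...] = GASTROINTESTINAL_ENZYMES
    pka_set: str = "classic"
    mass_table: str = "default"
    ph: float = 7.0
    threshold: float = 0.93
    out_dir: str = "pepdigest_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        self.enzymes = tuple(self.enzymes)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(self).items()},
                fh,
                sort_keys=False,
            )


def _load_scores(path: str | Path) -> dict[str, float]:
    entries = load_peptide_table(path, numeric_columns=("bioactivity_score",))
    return {
        e.sequence: float(e.annotations["bioactivity_score"])
        for e in entries
        if "bioactivity_score" in e.annotations
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full study on the configured inputs.

    Outputs (all CSV except the summary): ``fragments.csv`` with 1-based
    inclusive coordinates, ``profiles.csv`` with A/B/A_E/W per protein and
    activity class, ``physchem.csv`` for the distinct released peptides,
    ``summary.txt``, and ``resolved_config.yaml``.  Returns the written
    paths; on any stage failure, partial outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    if config.fasta is None:
        raise StageError("load", FileNotFoundError("no FASTA input configured"))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        proteins = parse_fasta(config.fasta)
        db = (
            load_activity_db(config.activity_db)
            if config.activity_db
            else resources.packaged_activity_db()
        )
        scores = _load_scores(config.scores) if config.scores else {}
        masses = load_mass_table(config.mass_table)
        pkas = load_pka_set(config.pka_set)
        enzymes = resolve_enzymes(config.enzymes)
        logger.info(
            "loaded %d proteins, %d activity records, enzymes: %s",
            len(proteins), len(db), ", ".join(config.enzymes),
        )

        stage = "digest"
        all_fragments = {p.accession: digest(p, enzymes) for p in proteins}
        frag_rows = []
        for protein in proteins:
            for frag in all_fragments[protein.accession]:
                frag_rows.append(
                    {
                        "protein": protein.accession,
                        "start": frag.start,
                        "end": frag.end,
                        "sequence": frag.sequence,
                        "label": f"{frag.sequence} {frag.coordinate_label()}",
                    }
                )
        frag_path = out_dir / "fragments.csv"
        write_table(pd.DataFrame(frag_rows), frag_path)
        written.append(frag_path)

        stage = "profile"
        profile_rows = []
        for protein in proteins:
            for cls in db.classes():
                prof, ae = profile_protein(
                    protein, all_fragments[protein.accession], db, cls
                )
                profile_rows.append(
                    {
                        "protein": protein.accession,
                        "fraction": protein.fraction.value,
                        "activity_class": cls,
                        "N": prof.N,
                        "A": round(prof.A, A_DECIMALS),
                        "B": round(prof.B, B_DECIMALS) if prof.b_defined else None,
                        "A_E": round(ae.A_E, A_DECIMALS),
                        "W": round(ae.W, A_DECIMALS) if ae.w_defined else None,
                    }
                )
        profile_path = out_dir / "profiles.csv"
        write_table(pd.DataFrame(profile_rows), profile_path)
        written.append(profile_path)

        stage = "physchem"
        released: dict[str, None] = {}
        active = set().union(*(db.peptides_for(c) for c in db.classes())) if db.classes() else set()
        for protein in proteins:
            for frag in all_fragments[protein.accession]:
                if frag.sequence in active:
                    released.setdefault(frag.sequence)
        peptides = [
            PeptideEntry(
                seq,
                {"bioactivity_score": scores[seq]} if seq in scores else {},
            )
            for seq in released
        ]
        records = physchem_report(peptides, masses=masses, pkas=pkas, ph=config.ph)
        phys_path = out_dir / "physchem.csv"
        write_table(report_dataframe(records), phys_path)
        written.append(phys_path)

        stage = "report"
        lines = [
            f"proteins analysed: {len(proteins)}",
            f"enzymes: {', '.join(config.enzymes)}",
            f"distinct active released peptides: {len(records)}",
        ]
        if records:
            seqs = [r.sequence for r in records]
            dist = length_distribution(seqs)
            lines.append(
                "length distribution: "
                + "; ".join(f"{k}-mers: {v.count} ({v.percent}%)" for k, v in dist.items())
            )
            comp = aa_composition(seqs)
            top = sorted(comp.percent.items(), key=lambda kv: -kv[1])[:5]
            lines.append(
                "top residues: " + ", ".join(f"{aa} {pct}%" for aa, pct in top)
            )
            if len(records) >= 2:
                mean, sd = mean_sd([r.mw for r in records])
                lines.append(f"mean molecular weight: {mean:.2f} g/mol (SD {sd:.2f})")
            if len(records) >= 3:
                try:
                    corr = pearson(
                        [r.pi for r in records],
                        [r.net_charge_ph for r in records],
                        "isoelectric_point",
                        "net_charge",
                    )
                    lines.append(f"Pearson r (pI vs net charge): {corr.r:.3f} (n={corr.n})")
                except PepdigestError:
                    pass
            if scores:
                scored = [r for r in records if r.bioactivity_score is not None]
                chosen = select_by_score(scored, config.threshold)
                lines.append(
                    f"candidates with score >= {config.threshold}: "
                    + ", ".join(r.sequence for r in chosen)
                )
        summary_path = out_dir / "summary.txt"
        summary_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(summary_path)

        config_path = out_dir / "resolved_config.yaml"
        config.to_yaml(config_path)
        written.append(config_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    return {p.stem: p for p in written}


def reproduce_reference() -> dict:
    """Recompute the desk-checkable reference-table numbers from fixtures.

    Returns a dictionary of computed statistics over the packaged
    released-peptide tables: recomputed vs printed molecular weights,
    printed-column mean/SD, pI-charge correlation, composition shares,
    dipeptide share, charge and solubility agreement, and the
    score-threshold selections.
    """
    entries = resources.packaged_physchem_entries()
    records = physchem_report(entries)
    by_seq = {r.sequence: r for r in records}
    printed = {
        e.sequence: e.annotations for e in entries
    }

    mw_mismatch = [
        seq
        for seq, ann in printed.items()
        if abs(by_seq[seq].mw - float(ann["molecular_weight"])) > 0.005
    ]
    charge_match = sum(
        1
        for seq, ann in printed.items()
        if abs(by_seq[seq].net_charge_ph - float(ann["net_charge"])) < 0.05
    )
    solubility_match = sum(
        1
        for seq, ann in printed.items()
        if by_seq[seq].solubility_label == ann["solubility"]
    )

    printed_mw = [float(ann["molecular_weight"]) for ann in printed.values()]
    mw_mean, mw_sd = mean_sd(printed_mw)
    corr = pearson(
        [float(ann["isoelectric_point"]) for ann in printed.values()],
        [float(ann["net_charge"]) for ann in printed.values()],
        "isoelectric_point",
        "net_charge",
    )

    seqs = [e.sequence for e in entries]
    comp = aa_composition(seqs)
    dist = length_distribution(seqs)

    high = select_by_score(records, 0.93)
    top = select_by_score(records, 0.99)

    return {
        "n_peptides": len(entries),
        "mw_recomputed": {seq: by_seq[seq].mw for seq in by_seq},
        "mw_mismatch_sequences": sorted(mw_mismatch),
        "printed_mw_mean": mw_mean,
        "printed_mw_sd": mw_sd,
        "pearson_pi_charge": corr.r,
        "composition_percent": comp.percent,
        "total_residues": comp.total_residues,
        "dipeptide_percent": dist[2].percent,
        "dipeptide_count": dist[2].count,
        "net_charge": {seq: by_seq[seq].net_charge_ph for seq in by_seq},
        "charge_match_count": charge_match,
        "solubility_match_count": solubility_match,
        "high_score_sequences": [r.sequence for r in high],
        "top_candidates": sorted(r.sequence for r in top),
    }
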