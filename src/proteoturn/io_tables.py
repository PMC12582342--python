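"""Delimited-text readers/writers and schema validation for the data bundle.

All tables are UTF-8 tab-separated text with a header row; protein
sequences travel as FASTA. Days are numeric relative to Day 0 and the
periods use the closed labels FL/EB/ED. ``SCHEMAS`` documents the
required columns of every table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import CohortDesign, GroundTruth, SimulatedCohort

SCHEMAS: dict[str, list[str]] = {
    "isotopomers": ["peptide_id", "accession", "subject", "period",
                    "boundary", "i_m0", "i_m1"],
    "lfq_peptides": ["accession", "peptide_id", "conflict"],  # + sample cols
    "gcms_standards": ["enrichment_pct", "rep", "i58", "i59"],
    "gcms_samples": ["subject", "period", "day", "rep", "i58", "i59"],
    "prm": ["target", "peptide", "sample", "fragment", "light_i", "heavy_i"],
    "physiology": ["subject", "period", "energy_intake_kcal", "eee_kcal",
                   "ffm_kg", "vo2_rest", "vco2_rest", "vo2_ex", "vco2_ex"],
    "annotation": ["accession", "compartment", "mw_kda"],
    "peptides": ["peptide_id", "accession", "sequence", "n_exch",
                 "ria_natural"],
}

_TABLES = ["isotopomers", "lfq_peptides", "gcms_standards", "gcms_samples",
           "prm", "physiology", "annotation"]


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for provenance."""
    payload = json.dumps(asdict(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bundle(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write a simulated cohort as a directory of TSV tables + FASTA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        write_table(getattr(cohort, name), out / f"{name}.tsv")
    write_table(cohort.truth.peptides, out / "peptides.tsv")
    write_table(cohort.truth.proteins.drop(columns="sequence"),
                out / "truth_proteins.tsv")
    write_table(cohort.truth.kinetics, out / "truth_kinetics.tsv")
    write_table(cohort.truth.enrichment, out / "truth_enrichment.tsv")
    records = [
        SeqRecord(Seq(seq), id=acc, description="synthetic")
        for acc, seq in cohort.fasta.items()
    ]
    SeqIO.write(records, out / "proteins.fasta", "fasta")
    (out / "design.json").write_text(
        json.dumps(asdict(cohort.design), indent=2, default=str)
    )
    return out


def read_bundle(bundle_dir: str | Path) -> SimulatedCohort:
    """Read a bundle directory back into a SimulatedCohort."""
    d = Path(bundle_dir)
    design = CohortDesign(**{
        k: tuple(tuple(x) for x in v) if isinstance(v, list) else v
        for k, v in json.loads((d / "design.json").read_text()).items()
    })
    fasta = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(d / "proteins.fasta", "fasta")
    }
    proteins = read_table(d / "truth_proteins.tsv")
    proteins["sequence"] = proteins["accession"].map(fasta)
    truth = GroundTruth(
        proteins=proteins,
        peptides=read_table(d / "peptides.tsv"),
        kinetics=read_table(d / "truth_kinetics.tsv"),
        enrichment=read_table(d / "truth_enrichment.tsv"),
    )
    tables = {name: read_table(d / f"{name}.tsv") for name in _TABLES}
    return SimulatedCohort(design=design, truth=truth, fasta=fasta, **tables)


def validate_tables(bundle_dir: str | Path) -> dict:
    """Per-file schema and sanity checks with row-level diagnostics.

    Returns {'valid': bool, 'files': {name: {'ok': bool, 'errors': [...]}}};
    unreadable files are reported, never raised past the report.
    """
    d = Path(bundle_dir)
    report: dict = {"files": {}}
    for name, required in SCHEMAS.items():
        path = d / f"{name}.tsv"
        entry: dict = {"ok": True, "errors": []}
        report["files"][name] = entry
        if not path.exists():
            if name == "peptides":
                continue
            entry["ok"] = False
            entry["errors"].append("file missing")
            continue
        try:
            df = read_table(path)
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            entry["ok"] = False
            entry["errors"].append(f"unreadable: {exc}")
            continue
        missing = [c for c in required if c not in df.columns]
        if missing:
            entry["ok"] = False
            entry["errors"].append(f"missing columns: {missing}")
            continue
        for col in ("i_m0", "i_m1", "i58", "i59", "light_i", "heavy_i"):
            if col in df.columns:
                bad = df.index[df[col] < 0].tolist()
                if bad:
                    entry["ok"] = False
                    entry["errors"].append(
                        f"negative {col} at rows {bad[:10]}"
                    )
        if name == "isotopomers":
            key = ["peptide_id", "subject", "period", "boundary"]
            dup = df.index[df.duplicated(key)].tolist()
            if dup:
                entry["ok"] = False
                entry["errors"].append(
                    f"duplicated (peptide, sample, boundary) at rows {dup[:10]}"
                )
    report["valid"] = all(e["ok"] for e in report["files"].values())
    return report
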