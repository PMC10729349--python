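"""Reading, writing and summarizing the single-phosphorus shift database.

Two on-disk formats are supported, mirroring the public deposit layout:

* **CSV** — one row per entry: id, sum formula, molecular weight, C/N/P/O
  counts, canonical SMILES, shift, solvent, reference, source and the
  precomputed environment label.  Derived columns are recomputed from the
  SMILES on read and cross-checked; mismatches are warnings, not errors.
* **SDF** (V2000) — one record per entry with the NMR information in data
  fields named after the NMReData convention: ``NMREDATA_ASSIGNMENT`` for
  the shift, ``NMREDATA_SOLVENT`` and ``NMREDATA_CITATION``; database
  bookkeeping lives in ``P31_ID`` and ``P31_SOURCE``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem
from .chem import (
    Composition,
    MolecularGraph,
    PhosphorusMultiplicityError,
)

CSV_COLUMNS = [
    "id",
    "sum_formula",
    "molecular_weight",
    "n_C",
    "n_N",
    "n_P",
    "n_O",
    "smiles",
    "shift_ppm",
    "solvent",
    "reference",
    "source",
    "env_label",
]

SOURCES = ("landolt", "handbook", "synthetic", "user")

TAG_ASSIGNMENT = "NMREDATA_ASSIGNMENT"
TAG_SOLVENT = "NMREDATA_SOLVENT"
TAG_CITATION = "NMREDATA_CITATION"
TAG_ID = "P31_ID"
TAG_SOURCE = "P31_SOURCE"


class SchemaError(ValueError):
    """A file does not conform to the expected database schema."""


@dataclass
class MoleculeRecord:
    """One database entry: structure, shift and provenance."""

    id: str
    graph: MolecularGraph
    smiles: str
    shift_ppm: float
    solvent: str | None = None
    reference: str = ""
    source: str = "user"
    env_label: str = ""
    composition: Composition | None = None

    @classmethod
    def from_graph(
        cls,
        id: str,
        graph: MolecularGraph,
        shift_ppm: float,
        solvent: str | None = None,
        reference: str = "",
        source: str = "user",
    ) -> "MoleculeRecord":
        """Build a record with all derived descriptors computed."""
        if not np.isfinite(shift_ppm):
            raise ValueError(f"record {id}: shift must be finite")
        return cls(
            id=id,
            graph=graph,
            smiles=chem.canonical_smiles(graph),
            shift_ppm=float(shift_ppm),
            solvent=solvent,
            reference=reference,
            source=source,
            env_label=chem.environment_label(graph),
            composition=chem.composition(graph),
        )


@dataclass
class DatabaseSummary:
    n_entries: int
    n_unique_molecules: int
    n_unique_references: int
    median_shift_ppm: float
    median_mw: float
    median_n_C: float
    subgroup_table: pd.DataFrame
    central_interval: tuple[float, float]


def records_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.composition or chem.composition(r.graph)
        rows.append(
            {
                "id": r.id,
                "sum_formula": c.sum_formula,
                "molecular_weight": c.molecular_weight,
                "n_C": c.n_C,
                "n_N": c.n_N,
                "n_P": c.n_P,
                "n_O": c.n_O,
                "smiles": r.smiles,
                "shift_ppm": r.shift_ppm,
                "solvent": r.solvent if r.solvent is not None else "",
                "reference": r.reference,
                "source": r.source,
                "env_label": r.env_label,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_csv_database(records: Sequence[MoleculeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv_database(path, column_map: dict[str, str] | None = None) -> list[MoleculeRecord]:
    """Load records from CSV; graphs are re-parsed from the SMILES column.

    Derived fields (composition, environment label) are recomputed and
    cross-checked against stored values; disagreements warn and the
    recomputed value is kept.  Rows whose molecule does not contain exactly
    one phosphorus atom are rejected with a multiplicity error.
    """
    df = pd.read_csv(path, dtype={"solvent": str, "reference": str})
    if column_map:
        df = df.rename(columns=column_map)
    mandatory = {"id", "smiles", "shift_ppm"}
    missing = mandatory - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        try:
            graph = chem.parse_structure(str(row["smiles"]), "smiles")
            rec = MoleculeRecord.from_graph(
                id=rid,
                graph=graph,
                shift_ppm=float(row["shift_ppm"]),
                solvent=_opt_str(row.get("solvent")),
                reference=_opt_str(row.get("reference")) or "",
                source=_opt_str(row.get("source")) or "user",
            )
        except (chem.ParseError, PhosphorusMultiplicityError) as e:
            raise SchemaError(f"row {rid}: {e}") from e
        for col, got in (
            ("env_label", rec.env_label),
            ("sum_formula", rec.composition.sum_formula),
        ):
            if col in df.columns and not pd.isna(row[col]) and str(row[col]) != got:
                warnings.warn(
                    f"row {rid}: stored {col} {row[col]!r} disagrees with "
                    f"recomputed {got!r}; keeping recomputed value"
                )
        records.append(rec)
    return records


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    s = str(v)
    return s if s else None


def write_sdf_nmredata(records: Sequence[MoleculeRecord], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = Chem.Mol(r.graph.mol)
            mol.SetProp("_Name", r.id)
            mol.SetProp(TAG_ID, r.id)
            # NMReData assignment line: label, shift, atom index (the P atom)
            p_idx = chem.find_phosphorus(r.graph)
            mol.SetProp(TAG_ASSIGNMENT, f"P1, {r.shift_ppm:.2f}, {p_idx + 1}")
            if r.solvent is not None:
                mol.SetProp(TAG_SOLVENT, r.solvent)
            if r.reference:
                mol.SetProp(TAG_CITATION, r.reference)
            mol.SetProp(TAG_SOURCE, r.source)
            writer.write(mol)
    finally:
        writer.close()


def read_sdf_nmredata(path) -> list[MoleculeRecord]:
    """Read NMReData-tagged SDF records; a record without a shift tag errors."""
    import os

    if os.path.getsize(str(path)) == 0:
        warnings.warn(f"{path}: empty file, no records")
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records = []
    n_seen = 0
    for mol in supplier:
        n_seen += 1
        if mol is None:
            raise SchemaError(f"unparsable SDF record #{n_seen}")
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record-{n_seen}"
        if not mol.HasProp(TAG_ASSIGNMENT):
            raise SchemaError(f"SDF record {title!r} lacks a {TAG_ASSIGNMENT} tag")
        shift = float(mol.GetProp(TAG_ASSIGNMENT).split(",")[1])
        rid = mol.GetProp(TAG_ID) if mol.HasProp(TAG_ID) else title
        records.append(
            MoleculeRecord.from_graph(
                id=rid,
                graph=MolecularGraph(mol),
                shift_ppm=shift,
                solvent=mol.GetProp(TAG_SOLVENT) if mol.HasProp(TAG_SOLVENT) else None,
                reference=mol.GetProp(TAG_CITATION) if mol.HasProp(TAG_CITATION) else "",
                source=mol.GetProp(TAG_SOURCE) if mol.HasProp(TAG_SOURCE) else "user",
            )
        )
    if not records:
        warnings.warn(f"{path}: no records found")
    return records


def filter_single_phosphorus(
    records: Iterable[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Partition records into (single-P kept, rejected)."""
    kept, rejected = [], []
    for r in records:
        try:
            chem.find_phosphorus(r.graph)
            kept.append(r)
        except PhosphorusMultiplicityError:
            rejected.append(r)
    return kept, rejected


def summarize(records: Sequence[MoleculeRecord]) -> DatabaseSummary:
    """Database statistics: medians, uniqueness counts, subgroup table and
    the central 95% shift interval (2.5th/97.5th linear-interpolation
    percentiles)."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    df = records_to_frame(records)
    shifts = df["shift_ppm"].to_numpy()
    sub = (
        df.groupby("env_label")
        .agg(
            frequency=("id", "size"),
            median_n_C=("n_C", "median"),
            median_mw=("molecular_weight", "median"),
            median_shift_ppm=("shift_ppm", "median"),
            shift_sd=("shift_ppm", lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0),
        )
        .sort_values(["frequency", "env_label"], ascending=[False, True])
        .reset_index()
    )
    refs = {r.reference.strip().lower() for r in records if r.reference.strip()}
    return DatabaseSummary(
        n_entries=len(records),
        n_unique_molecules=df["smiles"].nunique(),
        n_unique_references=len(refs),
        median_shift_ppm=float(np.median(shifts)),
        median_mw=float(df["molecular_weight"].median()),
        median_n_C=float(df["n_C"].median()),
        subgroup_table=sub,
        central_interval=(
            float(np.percentile(shifts, 2.5)),
            float(np.percentile(shifts, 97.5)),
        ),
    )


def subgroup_boxplot_data(
    records: Sequence[MoleculeRecord], n_groups: int = 19
) -> pd.DataFrame:
    """Per-subgroup box-plot statistics for the ``n_groups`` largest
    environment-label groups; everything else pooled under ``"Other"``."""
    df = records_to_frame(records)
    top = (
        df["env_label"].value_counts().head(n_groups).index.tolist()
        if len(df)
        else []
    )
    df = df.assign(
        group=df["env_label"].where(df["env_label"].isin(top), "Other")
    )
    rows = []
    for name, g in df.groupby("group"):
        s = g["shift_ppm"].to_numpy()
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "group": name,
                "n": len(s),
                "q1": q1,
                "median": med,
                "q3": q3,
                "lower_fence": q1 - 1.5 * iqr,
                "upper_fence": q3 + 1.5 * iqr,
            }
        )
    out = pd.DataFrame(rows).sort_values("n", ascending=False).reset_index(drop=True)
    # "Other" always sorts last regardless of size
    if "Other" in set(out["group"]):
        other = out[out["group"] == "Other"]
        out = pd.concat([out[out["group"] != "Other"], other]).reset_index(drop=True)
    return out
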