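"""Readers and writers for the package's CSV/TSV/FASTA/JSON interfaces."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import CELL_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_cell_table",
    "write_cell_table",
    "read_fasta",
    "write_fasta",
    "write_mutations_tsv",
    "write_json",
]

NUMERIC_COLUMNS = [
    "time_hr",
    "nuclear_area",
    "cyto_area",
    "cell_area",
    "nuclear_total",
    "cyto_total",
    "dapi_total",
]

AREA_COLUMNS = ["nuclear_area", "cyto_area", "cell_area"]


class SchemaError(ValueError):
    """Input table does not match the expected per-cell schema."""


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a per-cell HCS feature table (CSV).

    A missing column raises :class:`SchemaError` naming it.  Rows with
    non-numeric or non-positive areas, or negative intensities, are rejected
    individually with their row numbers logged; remaining rows are returned
    typed.
    """
    path = Path(path)
    # round_trip parsing so write -> read reproduces values bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CELL_COLUMNS if c not in df.columns and c != "phase_true"]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[NUMERIC_COLUMNS].isna().any(axis=1)
    bad |= (df[AREA_COLUMNS] <= 0).any(axis=1)
    bad |= (df[["nuclear_total", "cyto_total", "dapi_total"]] < 0).any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:20]]  # +2: header + 1-based
        logger.warning(
            "%s: rejected %d malformed row(s) (file line numbers %s%s)",
            path.name,
            int(bad.sum()),
            rows,
            "..." if bad.sum() > 20 else "",
        )
    return df.loc[~bad].reset_index(drop=True)


def write_cell_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in CELL_COLUMNS if c in df.columns]
    df[cols + [c for c in df.columns if c not in cols]].to_csv(path, index=False)


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_mutations_tsv(sets: list, path) -> None:
    """Write mutation calls as a TSV with cell_id, kind, position, ref, alt."""
    rows = [
        {"cell_id": ms.cell_id, "kind": m.kind, "position": m.position, "ref": m.ref, "alt": m.alt}
        for ms in sets
        for m in sorted(ms.mutations)
    ]
    pd.DataFrame(rows, columns=["cell_id", "kind", "position", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
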