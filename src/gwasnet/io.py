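"""Flat-file readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .scoring import GeneRecord

REQUIRED_GENE_COLUMNS = ("gene_id", "min_p", "n_snps", "n_pubs")


def read_gene_table(path) -> list:
    """Read a TSV gene table into GeneRecords.

    Required columns: gene_id, min_p, n_snps, n_pubs.  Optional: traits
    (semicolon-separated) and any number of ``q_<tissue>`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    q_cols = [c for c in df.columns if c.startswith("q_")]
    records = []
    for row in df.itertuples(index=False):
        traits = frozenset()
        if "traits" in df.columns and isinstance(row.traits, str) and row.traits:
            traits = frozenset(t for t in row.traits.split(";") if t)
        eqtl = {}
        for c in q_cols:
            val = getattr(row, c)
            if pd.notna(val) and val != "":
                eqtl[c[2:]] = float(val)
        records.append(GeneRecord(
            gene_id=row.gene_id,
            min_p=float(row.min_p),
            n_snps=int(row.n_snps),
            n_pubs=int(row.n_pubs),
            traits=traits,
            eqtl_q=eqtl or None,
        ))
    return records


def read_gene_map(path) -> dict:
    """gene_id -> list of protein ids, from a two-column TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "protein_id"]:
        raise ValidationError(
            f"{path}: expected columns gene_id, protein_id")
    mapping: dict[str, list] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.gene_id, []).append(row.protein_id)
    return mapping


def write_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")
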