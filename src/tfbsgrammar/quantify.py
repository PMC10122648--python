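"""Barcode counts -> per-tile expression.

Follows the standard reporter-assay quantification chain: drop barcodes
with low DNA representation, drop tiles left with too few barcodes in a
replicate, convert each barcode to a depth-normalized log2(RNA/DNA), then
average barcodes within a replicate and replicates within a tile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "filter_barcodes",
    "normalize_expression",
    "aggregate_tiles",
    "replicate_correlation",
    "quantify",
]

logger = logging.getLogger(__name__)

_REQUIRED = ("tile_id", "barcode_id", "replicate", "dna_count", "rna_count")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")


def filter_barcodes(
    table: pd.DataFrame, min_count: int = 3, min_barcodes: int = 3
) -> pd.DataFrame:
    """Apply the two representation filters.

    Barcodes with ``dna_count < min_count`` are removed (the boundary value
    is retained); tiles then retaining fewer than ``min_barcodes`` barcodes
    within a replicate are dropped for that replicate.
    """
    _check_table(table)
    kept = table[table["dna_count"] >= min_count]
    n_bc_removed = len(table) - len(kept)
    sizes = kept.groupby(["tile_id", "replicate"])["barcode_id"].transform("size")
    out = kept[sizes >= min_barcodes].reset_index(drop=True)
    logger.info(
        "filter_barcodes: removed %d barcodes (dna<%d) and %d rows in "
        "under-represented tile-replicates (<%d barcodes)",
        n_bc_removed, min_count, len(kept) - len(out), min_barcodes,
    )
    if out.empty:
        logger.warning("filter_barcodes: no rows survive filtering")
    return out


def normalize_expression(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-barcode expression = log2 of depth-normalized RNA/DNA ratio.

    Library totals are computed per replicate.  Barcodes with zero RNA get
    the pseudocount added to both counts so the ratio stays finite.
    """
    _check_table(table)
    df = table.copy()
    dna = df["dna_count"].astype(float)
    rna = df["rna_count"].astype(float)
    zero = rna == 0
    rna = rna + pseudocount * zero
    dna = dna + pseudocount * zero
    totals = df.groupby("replicate").agg(
        dna_total=("dna_count", "sum"), rna_total=("rna_count", "sum")
    )
    df["expression"] = np.log2(
        (rna / df["replicate"].map(totals["rna_total"]))
        / (dna / df["replicate"].map(totals["dna_total"]))
    )
    return df


def aggregate_tiles(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean barcode expression per tile x replicate, plus a combined mean.

    Returns a wide table: tile_id, one ``rep<k>`` column per replicate, the
    per-replicate barcode counts ``n_barcodes_rep<k>`` and ``combined`` =
    mean across replicates present for that tile.
    """
    if "expression" not in normalized.columns:
        raise ValueError("run normalize_expression first")
    g = normalized.groupby(["tile_id", "replicate"])["expression"].agg(["mean", "size"])
    wide = g["mean"].unstack("replicate")
    sizes = g["size"].unstack("replicate")
    out = pd.DataFrame(index=wide.index)
    for rep in wide.columns:
        out[f"rep{rep}"] = wide[rep]
        out[f"n_barcodes_rep{rep}"] = sizes[rep].fillna(0).astype(int)
    out["combined"] = wide.mean(axis=1)
    return out.reset_index()


def replicate_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-replicate tile expression."""
    reps = [c for c in expr.columns if c.startswith("rep") and not c.startswith("rep_")]
    reps = [c for c in reps if expr[c].dtype.kind == "f" or expr[c].dtype.kind == "i"]
    if len(reps) < 2:
        raise ValueError("need at least two replicate columns")
    shared = expr[reps].dropna()
    if len(shared) < 3:
        raise ValueError("need at least three tiles shared across replicates")
    return shared.corr(method="pearson")


def quantify(
    table: pd.DataFrame, min_count: int = 3, min_barcodes: int = 3
) -> pd.DataFrame:
    """Full chain: filter -> normalize -> aggregate."""
    return aggregate_tiles(normalize_expression(filter_barcodes(table, min_count, min_barcodes)))
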