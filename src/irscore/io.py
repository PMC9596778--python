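"""Readers and writers for the external formats the pipeline touches.

GMT (Broad dialect) for gene-set collections, delimited TSV/CSV for bulk
expression and clinical tables, MatrixMarket triplets (matrix.mtx +
features/barcodes sidecars) for single-cell counts.  Every loader validates
into the domain types; nothing is silently imputed or dropped.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CohortDataset,
    EnrichmentMatrix,
    ExpressionMatrix,
    SignatureCollection,
    SurvivalTable,
)

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path, source_tag: str | None = None) -> SignatureCollection:
    """Read a Broad-dialect GMT file: name, description, then gene IDs.

    Duplicate genes within a line are collapsed; duplicate set names or lines
    with fewer than three fields are errors (with the offending line number).
    """
    path = Path(path)
    gene_sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0]
            if name in gene_sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            gene_sets[name] = genes
    return SignatureCollection(gene_sets, source_tag or str(path))


def write_gmt(sigs: SignatureCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sigs.gene_sets.items():
            fh.write("\t".join([name, sigs.source_tag or "na", *genes]) + "\n")


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_expression(
    path: str | Path,
    layout: str = "genes_in_rows",
    scale_tag: str = "log2",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into genes x samples orientation.

    ``layout`` says which axis the file's rows represent; the returned matrix
    is always genes x samples.  Tab is the default delimiter, comma is
    auto-detected from the header.  Any non-numeric or missing cell is an
    error with its coordinates (via ExpressionMatrix validation).
    ``log2_transform`` applies log2(x+1) on load for count-scale inputs.
    """
    path = Path(path)
    if layout not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise ValueError(
            f"{path}: non-numeric cell at row={where!r}, column={col!r}"
        )
    if layout == "samples_in_rows":
        df = df.T
    if log2_transform:
        df = np.log2(df + 1.0)
        scale_tag = "log2"
    return ExpressionMatrix(df, scale_tag)  # validates IDs / NaNs


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    # %.17g keeps the write->read round trip exact at double precision
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_mtx_triplet(
    matrix: str | Path, features: str | Path, barcodes: str | Path
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix with feature/barcode sidecars.

    Convention is genes in rows, cells in columns (the cellranger layout).
    Sidecar line counts must match the MTX header dimensions.  All-zero
    columns (empty cells) are retained and logged, never dropped.
    """
    mat = scipy.io.mmread(str(matrix))
    genes = [ln.split("\t")[0] for ln in Path(features).read_text().splitlines() if ln]
    cells = [ln.split("\t")[0] for ln in Path(barcodes).read_text().splitlines() if ln]
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise ValueError(
            f"features file has {len(genes)} lines but matrix header says {n_genes}"
        )
    if len(cells) != n_cells:
        raise ValueError(
            f"barcodes file has {len(cells)} lines but matrix header says {n_cells}"
        )
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    empty = int((dense.sum(axis=0) == 0).sum())
    if empty:
        logger.warning("MTX load: %d all-zero columns (empty cells) retained", empty)
    df = pd.DataFrame(dense, index=genes, columns=cells)
    return ExpressionMatrix(df, scale_tag="counts")


def write_mtx_triplet(
    expr: ExpressionMatrix, matrix: str | Path, features: str | Path, barcodes: str | Path
) -> None:
    sparse = scipy.sparse.coo_matrix(expr.data.to_numpy())
    scipy.io.mmwrite(str(matrix), sparse)
    Path(features).write_text("".join(f"{g}\n" for g in expr.gene_ids))
    Path(barcodes).write_text("".join(f"{c}\n" for c in expr.sample_ids))


def read_survival(path: str | Path, time_unit: str = "months") -> SurvivalTable:
    """Clinical TSV/CSV with columns sample_id, time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    return SurvivalTable(df.set_index("sample_id"), time_unit)


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    surv.data.to_csv(path, sep="\t", index_label="sample_id")


def read_cohort(
    name: str, expression_path: str | Path, survival_path: str | Path, **expr_kwargs
) -> CohortDataset:
    expr = read_expression(expression_path, **expr_kwargs)
    surv = read_survival(survival_path)
    return CohortDataset(name, expr, surv)


def write_enrichment(enr: EnrichmentMatrix, path: str | Path) -> None:
    enr.scores.to_csv(path, sep="\t", index_label="signature")


def read_enrichment(path: str | Path, variant: str = "raw_es") -> EnrichmentMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EnrichmentMatrix(df, variant=variant)
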