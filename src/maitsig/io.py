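"""Readers and writers for the package's plain-text interchange formats.

Expression matrices travel either as MatrixMarket triplets with two
single-column sidecar files (genes, cells) or as dense TSV with genes as
rows.  Annotations, TCR contigs and bulk cohorts are TSV with headers;
gene sets are YAML.
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    BulkCohort,
    GeneExpressionMatrix,
    StructuralError,
    validate_annotations,
)

Layer = Literal["counts", "normexpr"]


def _read_sidecar(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    path: str,
    format: Literal["mtx", "tsv"] = "tsv",
    layer: Layer = "counts",
) -> GeneExpressionMatrix:
    """Read an expression matrix into the declared layer.

    ``mtx``: ``path`` is the .mtx triplet file; gene and cell sidecars are
    expected next to it as ``<stem>.genes.txt`` / ``<stem>.cells.txt``.
    ``tsv``: dense table, genes as rows, first column gene symbols, header
    row of cell ids.
    """
    if format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        genes = _read_sidecar(stem + ".genes.txt")
        cells = _read_sidecar(stem + ".cells.txt")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy's message carries the line
            raise StructuralError(f"malformed MatrixMarket file {path}: {exc}") from exc
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(cells)):
            raise StructuralError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    elif format == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise StructuralError(f"malformed TSV {path}: {exc}") from exc
        genes = [str(g) for g in frame.index]
        cells = [str(c) for c in frame.columns]
        dense = frame.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format '{format}' (expected 'mtx' or 'tsv')")
    kwargs = {layer: dense}
    return GeneExpressionMatrix(gene_ids=genes, cell_ids=cells, **kwargs)


def write_expression(
    matrix: GeneExpressionMatrix,
    path: str,
    format: Literal["mtx", "tsv"] = "tsv",
    layer: Layer = "counts",
) -> None:
    """Write one layer of a matrix in the given format (inverse of read)."""
    data = getattr(matrix, layer)
    if data is None:
        raise StructuralError(f"matrix has no '{layer}' layer")
    if format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        scipy.io.mmwrite(stem + ".mtx", scipy.sparse.coo_matrix(data))
        with open(stem + ".genes.txt", "w") as fh:
            fh.write("\n".join(matrix.gene_ids) + "\n")
        with open(stem + ".cells.txt", "w") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
    elif format == "tsv":
        pd.DataFrame(data, index=matrix.gene_ids, columns=matrix.cell_ids).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown format '{format}'")


def read_annotations(path: str) -> pd.DataFrame:
    """Read a cell annotation TSV (cell_id, patient_id, tissue, subset, treatment)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotations(ann)


def write_annotations(annotations: pd.DataFrame, path: str) -> None:
    validate_annotations(annotations).to_csv(path, sep="\t", index=False)


def read_contigs(path: str) -> pd.DataFrame:
    """Read TCR contig records, one chain per row.

    Columns: cell_id, locus, v_gene, j_gene, cdr3_nt, cdr3_aa, productive.
    ``productive`` accepts True/False/true/false/1/0 (10x-style exports).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cell_id", "locus", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa", "productive"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructuralError(f"contig table missing columns: {missing}")
    df = df.loc[:, required].copy()
    truthy = {"true": True, "false": False, "1": True, "0": False}
    df["productive"] = df["productive"].str.strip().str.lower().map(truthy)
    if df["productive"].isna().any():
        raise StructuralError("contig table has unparsable 'productive' values")
    return df


def read_bulk_cohort(expr_path: str, clinical_path: str) -> BulkCohort:
    """Read a bulk cohort: sample x gene log2(TPM+1) TSV plus clinical TSV."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    clinical = pd.read_csv(clinical_path, sep="\t", index_col=0)
    clinical.index = clinical.index.astype(str)
    missing = [s for s in expr.index if s not in clinical.index]
    if missing:
        raise StructuralError(f"samples without clinical rows: {missing[:10]}")
    return BulkCohort(expr=expr, clinical=clinical.loc[expr.index])


def write_bulk_cohort(cohort: BulkCohort, expr_path: str, clinical_path: str) -> None:
    cohort.expr.to_csv(expr_path, sep="\t")
    cohort.clinical.to_csv(clinical_path, sep="\t")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
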