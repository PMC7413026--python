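"""Quality-control filters and library-size normalization.

Cell filters follow droplet-platform conventions: bounds on total UMI,
on detected-gene counts and on the mitochondrial fraction.  Bound
semantics mirror the written thresholds: "< min" removes strictly below
the minimum (cells exactly at the bound are kept) and "> max" removes
strictly above.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .datatypes import ConfigError, GeneExpressionMatrix, StructuralError


def qc_filter_cells(
    matrix: GeneExpressionMatrix,
    annotations: pd.DataFrame,
    min_umi: float = 1200,
    max_umi: float = 25000,
    min_genes: int = 600,
    max_genes: int = 4000,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "MT-",
) -> Tuple[GeneExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells; annotations are subset to the survivors.

    A cell is kept iff min_umi <= UMI <= max_umi, min_genes <= detected
    genes <= max_genes, and mitochondrial fraction <= max_mito_frac.
    Mitochondrial genes are identified by symbol prefix (default "MT-").
    """
    if matrix.counts is None:
        raise StructuralError("qc_filter_cells requires a counts layer")
    if min_umi > max_umi or min_genes > max_genes:
        raise ConfigError("QC thresholds inverted (min > max)")
    if not 0 <= max_mito_frac <= 1:
        raise ConfigError("max_mito_frac must be in [0, 1]")

    counts = matrix.counts
    umi = counts.sum(axis=0)
    n_genes = (counts > 0).sum(axis=0)
    mito_mask = np.array([g.startswith(mito_prefix) for g in matrix.gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, counts[mito_mask, :].sum(axis=0) / umi, 0.0)

    keep = (
        (umi >= min_umi)
        & (umi <= max_umi)
        & (n_genes >= min_genes)
        & (n_genes <= max_genes)
        & (mito_frac <= max_mito_frac)
    )
    filtered = matrix.subset_cells(keep)
    kept_ids = set(filtered.cell_ids)
    ann = annotations[annotations["cell_id"].isin(kept_ids)].reset_index(drop=True)
    return filtered, ann


def filter_low_genes(
    matrix: GeneExpressionMatrix, min_mean_count: float = 0.01
) -> GeneExpressionMatrix:
    """Drop genes whose average count across all cells is below the threshold."""
    if matrix.counts is None:
        raise StructuralError("filter_low_genes requires a counts layer")
    keep = matrix.counts.mean(axis=1) >= min_mean_count
    if not keep.any():
        import warnings

        warnings.warn("no gene passes the mean-count filter; returning empty matrix")
    return matrix.subset_genes(keep)


def normalize_log_cpm(counts: np.ndarray, cell_ids=None) -> np.ndarray:
    """log2(1e6 * count / library_size + 1) per cell (counts per million).

    Zero counts map to exactly 0; values within a cell are invariant to a
    uniform rescaling of that cell's counts.
    """
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = np.flatnonzero(libsize <= 0)
        names = (
            [cell_ids[i] for i in bad[:5]] if cell_ids is not None else bad[:5].tolist()
        )
        raise StructuralError(f"zero library size for cells: {names}")
    return np.log2(1e6 * counts / libsize + 1.0)


def add_normexpr(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Return a copy of the matrix with a log2-CPM normexpr layer."""
    if matrix.counts is None:
        raise StructuralError("add_normexpr requires a counts layer")
    return GeneExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        counts=matrix.counts,
        normexpr=normalize_log_cpm(matrix.counts, matrix.cell_ids),
    )
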