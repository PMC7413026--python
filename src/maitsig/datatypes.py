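"""Core containers shared by every pipeline stage.

The package works on three kinds of objects: a genes x cells expression
matrix with one or two layers (raw counts and/or log2-normalized values),
a per-cell annotation table, and a bulk cohort (sample x gene expression
plus survival endpoints).  Containers are deliberately thin wrappers around
numpy arrays / pandas frames with validation at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TISSUES = ("blood", "normal", "tumor")
SUBSETS = ("MAIT", "CD8", "CD4", "Treg", "other", "unassigned")
TREATMENTS = ("pre", "post", "not_applicable")

ANNOTATION_COLUMNS = ("cell_id", "patient_id", "tissue", "subset", "treatment")


class MaitsigError(Exception):
    """Base class for package errors."""


class ConfigError(MaitsigError):
    """Invalid user-supplied configuration (inverted thresholds, bad enums...)."""


class StructuralError(MaitsigError):
    """Inconsistent data structure (dimension mismatches, duplicate ids...)."""


@dataclass
class GeneExpressionMatrix:
    """Genes x cells expression with optional ``counts`` and ``normexpr`` layers.

    ``counts`` holds non-negative UMI/read counts; ``normexpr`` holds values on
    a log2(x+1) scale (log2-CPM or log2-TPM).  At least one layer must be
    present, and layer shapes must match ``(len(gene_ids), len(cell_ids))``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: Optional[np.ndarray] = None
    normexpr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise StructuralError(f"duplicate gene symbols: {dupes[:10]}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise StructuralError("duplicate cell identifiers")
        if self.counts is None and self.normexpr is None:
            raise StructuralError("at least one layer (counts or normexpr) required")
        shape = (len(self.gene_ids), len(self.cell_ids))
        for name in ("counts", "normexpr"):
            layer = getattr(self, name)
            if layer is None:
                continue
            layer = np.asarray(layer, dtype=float)
            if layer.shape != shape:
                raise StructuralError(
                    f"layer '{name}' has shape {layer.shape}, expected {shape}"
                )
            if name == "counts" and (layer < 0).any():
                raise StructuralError("counts layer contains negative entries")
            setattr(self, name, layer)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Integer positions of ``genes`` (all must be present)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, keep: np.ndarray) -> "GeneExpressionMatrix":
        keep = np.asarray(keep)
        return GeneExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.gene_ids[i] for i in keep],
            cell_ids=list(self.cell_ids),
            counts=None if self.counts is None else self.counts[keep, :],
            normexpr=None if self.normexpr is None else self.normexpr[keep, :],
        )

    def subset_cells(self, keep: np.ndarray) -> "GeneExpressionMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GeneExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=None if self.counts is None else self.counts[:, idx],
            normexpr=None if self.normexpr is None else self.normexpr[:, idx],
        )


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell annotation table and return a normalized copy.

    Required columns: cell_id, patient_id, tissue, subset, treatment.
    tissue/subset/treatment are restricted to their enumerations; each
    cell_id may appear at most once.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise StructuralError(f"annotation table missing columns: {missing}")
    ann = annotations.loc[:, list(ANNOTATION_COLUMNS)].copy()
    ann["cell_id"] = ann["cell_id"].astype(str)
    if ann["cell_id"].duplicated().any():
        raise StructuralError("annotation table has duplicate cell_id rows")
    for col, allowed in (
        ("tissue", TISSUES),
        ("subset", SUBSETS),
        ("treatment", TREATMENTS),
    ):
        bad = sorted(set(ann[col]) - set(allowed))
        if bad:
            raise ConfigError(f"invalid {col} values {bad}; allowed: {allowed}")
    return ann


def align_annotations(
    matrix: GeneExpressionMatrix, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Subset and order the annotation table to the matrix's cells."""
    ann = validate_annotations(annotations).set_index("cell_id")
    missing = [c for c in matrix.cell_ids if c not in ann.index]
    if missing:
        raise StructuralError(f"cells without annotation: {missing[:10]}")
    return ann.loc[matrix.cell_ids].reset_index()


@dataclass
class BulkCohort:
    """A bulk expression cohort: sample x gene log2(TPM+1) plus endpoints.

    ``expr`` is a DataFrame indexed by sample_id with gene symbols as columns.
    ``clinical`` carries os_time/os_event/pfs_time/pfs_event per sample
    (times in days, events binary 0/1).
    """

    expr: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.expr.to_numpy(dtype=float)).all():
            raise StructuralError("bulk expression contains non-finite values")
        required = ("os_time", "os_event", "pfs_time", "pfs_event")
        missing = [c for c in required if c not in self.clinical.columns]
        if missing:
            raise StructuralError(f"clinical table missing columns: {missing}")
        clin = self.clinical.loc[self.expr.index]
        for t, e in (("os_time", "os_event"), ("pfs_time", "pfs_event")):
            times = clin[t].to_numpy(dtype=float)
            events = clin[e].to_numpy(dtype=float)
            if (times < 0).any():
                raise StructuralError(f"{t} contains negative times")
            if not np.isin(events, (0.0, 1.0)).all():
                raise StructuralError(f"{e} must be binary 0/1")
        self.clinical = clin

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.columns)


@dataclass
class SignatureDefinition:
    """A named gene set with provenance (paper_default, derived, or user)."""

    name: str
    genes: list[str]
    provenance: str = "user"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"signature '{self.name}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError(f"signature '{self.name}' has duplicate genes")
        if self.provenance not in ("paper_default", "derived", "user"):
            raise ConfigError(f"invalid provenance '{self.provenance}'")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
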