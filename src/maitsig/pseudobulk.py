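"""Pseudo-bulk simulation and signature-vs-frequency evaluation.

Pseudo-bulk samples are formed by drawing n cells without replacement
from an annotated single-cell counts matrix and summing raw UMI counts
per gene.  Because the sampled cells' identities are known, each
sample carries ground-truth subset fractions.  The sample-level MAIT
score is the plain mean of log2(CPM+1) expression of the (low-expression
pre-filtered) signature genes; its Pearson correlation with the true
MAIT fraction quantifies how well the signature tracks abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import ConfigError, GeneExpressionMatrix, SignatureDefinition
from .stats import mad_outlier_mask

TRACKED_SUBSETS = ("MAIT", "CD8", "CD4", "Treg")


@dataclass
class PseudoBulkConfig:
    """Simulation settings.

    n_cells may be a fixed integer or an inclusive integer range (lo, hi)
    sampled uniformly per sample.  An explicit seed is mandatory: every
    randomized operation in the package refuses to run without one.
    """

    n_samples: int
    n_cells: Union[int, tuple[int, int]]
    seed: Optional[int] = None
    low_expression_prefilter: float = 0.01
    outlier_mad_k: float = 3.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.seed is None:
            raise ConfigError("an explicit integer seed is required")
        if isinstance(self.n_cells, tuple):
            lo, hi = self.n_cells
            if lo < 1 or hi < lo:
                raise ConfigError("n_cells range must satisfy 1 <= lo <= hi")
        elif self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")


@dataclass
class PseudoBulkSample:
    sample_id: str
    counts: np.ndarray  # summed counts per gene
    n_cells: int
    fractions: dict  # subset -> true fraction among sampled cells
    normexpr: np.ndarray  # log2(CPM+1) per gene
    mait_score: float = np.nan


def prefilter_signature(
    matrix: GeneExpressionMatrix,
    signature: SignatureDefinition | Sequence[str],
    min_expr_frac: float = 0.01,
) -> SignatureDefinition:
    """Drop signature genes detected (count > 0) in too few cells.

    Mirrors the removal of lowly expressed signature genes from droplet
    datasets before pseudo-bulk scoring.
    """
    genes = list(signature.genes if isinstance(signature, SignatureDefinition) else signature)
    if matrix.counts is None:
        raise ConfigError("prefilter_signature requires a counts layer")
    present = [g for g in genes if g in set(matrix.gene_ids)]
    idx = matrix.gene_index(present)
    det_frac = (matrix.counts[idx, :] > 0).mean(axis=1)
    kept = [g for g, f in zip(present, det_frac) if f >= min_expr_frac]
    removed = sorted(set(genes) - set(kept))
    if not kept:
        raise ConfigError("all signature genes removed by the expression pre-filter")
    if removed:
        import logging

        logging.getLogger(__name__).info(
            "prefilter_signature removed %d genes: %s", len(removed), removed
        )
    return SignatureDefinition("mait_signature_prefiltered", kept, "derived")


def make_pseudobulk(
    matrix: GeneExpressionMatrix,
    annotations: pd.DataFrame,
    config: PseudoBulkConfig,
    signature: SignatureDefinition | Sequence[str] | None = None,
    zscore: bool = False,
) -> list[PseudoBulkSample]:
    """Draw pseudo-bulk samples and score them with the MAIT signature.

    Sampling is without replacement within a sample and independent
    across samples.  The default score is the unweighted mean of the
    signature genes' log2(CPM+1); ``zscore=True`` switches to the
    per-cell-style mean-of-z rule computed across samples.
    """
    if matrix.counts is None:
        raise ConfigError("make_pseudobulk requires a counts layer")
    rng = np.random.default_rng(config.seed)
    n_available = matrix.n_cells
    ann = annotations.set_index("cell_id").loc[matrix.cell_ids]
    subsets = ann["subset"].to_numpy()
    samples: list[PseudoBulkSample] = []
    for i in range(config.n_samples):
        if isinstance(config.n_cells, tuple):
            n = int(rng.integers(config.n_cells[0], config.n_cells[1] + 1))
        else:
            n = int(config.n_cells)
        if n > n_available:
            raise ConfigError(
                f"requested {n} cells but only {n_available} are available"
            )
        idx = rng.choice(n_available, size=n, replace=False)
        counts = matrix.counts[:, idx].sum(axis=1)
        libsize = counts.sum()
        if libsize <= 0:
            raise ConfigError(f"pseudo-bulk sample {i} has zero total counts")
        normexpr = np.log2(1e6 * counts / libsize + 1.0)
        chosen = subsets[idx]
        fractions = {s: float((chosen == s).mean()) for s in TRACKED_SUBSETS}
        samples.append(
            PseudoBulkSample(
                sample_id=f"pb{i:04d}",
                counts=counts,
                n_cells=n,
                fractions=fractions,
                normexpr=normexpr,
            )
        )
    if signature is not None:
        genes = list(
            signature.genes if isinstance(signature, SignatureDefinition) else signature
        )
        idx = matrix.gene_index([g for g in genes if g in set(matrix.gene_ids)])
        if idx.size == 0:
            raise ConfigError("no signature gene present in matrix")
        expr = np.stack([s.normexpr[idx] for s in samples])  # samples x genes
        if zscore:
            mean = expr.mean(axis=0, keepdims=True)
            sd = expr.std(axis=0, ddof=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                expr = np.where(sd > 0, (expr - mean) / sd, 0.0)
        scores = expr.mean(axis=1)
        for s, sc in zip(samples, scores):
            s.mait_score = float(sc)
    return samples


def samples_to_frame(samples: Sequence[PseudoBulkSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "n_cells": s.n_cells, "mait_score": s.mait_score}
        row.update({f"frac_{k}": v for k, v in s.fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_scores(
    samples: Sequence[PseudoBulkSample], outlier_mad_k: float = 3.0
) -> dict:
    """Correlate MAIT scores with true subset fractions after outlier removal.

    Samples whose MAIT score lies farther than k raw MADs from the median
    score are removed once; Pearson r and two-sided p are then computed
    against each tracked subset's true fraction on the surviving samples.
    """
    scores = np.array([s.mait_score for s in samples], dtype=float)
    if np.isnan(scores).any():
        raise ConfigError("samples lack MAIT scores; pass a signature to make_pseudobulk")
    outliers = mad_outlier_mask(scores, k=outlier_mad_k)
    keep = ~outliers
    if keep.sum() < 3:
        raise ConfigError("fewer than 3 samples remain after outlier removal")
    report: dict = {
        "n_samples": int(len(samples)),
        "n_outliers_removed": int(outliers.sum()),
        "outlier_ids": [s.sample_id for s, o in zip(samples, outliers) if o],
        "correlations": {},
    }
    for subset in TRACKED_SUBSETS:
        frac = np.array([s.fractions[subset] for s in samples], dtype=float)[keep]
        kept_scores = scores[keep]
        if np.all(frac == frac[0]) or np.all(kept_scores == kept_scores[0]):
            r, p = 0.0, 1.0
        else:
            r, p = scipy.stats.pearsonr(scores[keep], frac)
        report["correlations"][subset] = {"r": float(r), "p": float(p)}
    return report
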