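"""Per-cell module scoring and consensus MAIT-signature derivation.

A module score is the per-cell mean of per-gene z-scores of log2
expression; rank-based two-group comparisons use the Wilcoxon rank-sum
test.  The consensus signature is the strict intersection, across
cancer x tissue strata, of genes significantly higher in MAIT cells
than in EVERY comparator T-cell subset within the stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import ConfigError, GeneExpressionMatrix, SignatureDefinition
from .diffexpr import DegConfig, moderated_fit, moderated_t_test


@dataclass
class CellScoreVector:
    cell_ids: list[str]
    score: np.ndarray
    genes_used: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "score": self.score})


def score_module(
    matrix: GeneExpressionMatrix,
    signature: SignatureDefinition | Sequence[str],
    layer: str = "normexpr",
) -> CellScoreVector:
    """Mean-of-z module score per cell.

    Per gene, z = (x - mean over cells) / sd over cells (sample sd); the
    cell's score is the mean of z over the signature genes present in the
    matrix.  Constant genes contribute 0 to every cell.
    """
    genes = list(signature.genes if isinstance(signature, SignatureDefinition) else signature)
    data = getattr(matrix, layer)
    if data is None:
        raise ConfigError(f"matrix has no '{layer}' layer")
    present = [g for g in genes if g in set(matrix.gene_ids)]
    if not present:
        raise ConfigError(f"no signature gene present in matrix; missing: {genes}")
    idx = matrix.gene_index(present)
    sub = data[idx, :]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (sub - mean) / sd, 0.0)
    return CellScoreVector(
        cell_ids=list(matrix.cell_ids),
        score=z.mean(axis=0),
        genes_used=present,
    )


def compare_scores(scores: np.ndarray, group_labels: Sequence) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    Exact null enumeration when both groups have <= 25 observations and
    the data are tie-free; the tie-corrected normal approximation
    otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    names = pd.unique(labels)
    if len(names) != 2:
        raise ConfigError(f"compare_scores expects exactly 2 groups, got {list(names)}")
    a = scores[labels == names[0]]
    b = scores[labels == names[1]]
    if a.size == 0 or b.size == 0:
        raise ConfigError("both groups must be non-empty")
    tie_free = len(np.unique(scores)) == scores.size
    method = "exact" if (max(a.size, b.size) <= 25 and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
        "groups": [str(names[0]), str(names[1])],
        "n": [int(a.size), int(b.size)],
    }


@dataclass
class Stratum:
    """One cancer x tissue block of cells used for consensus derivation."""

    cancer: str
    tissue: str
    matrix: GeneExpressionMatrix
    subsets: np.ndarray  # per-cell subset labels, aligned to matrix.cell_ids


@dataclass
class ConsensusResult:
    genes: list[str]
    per_stratum: dict  # (cancer, tissue-label) -> sorted qualifying gene list
    n_sets: int

    def signature(self) -> SignatureDefinition:
        return SignatureDefinition("mait_consensus", list(self.genes), "derived")


def _merge_low_mait_strata(
    strata: Sequence[Stratum], min_mait: int
) -> list[Stratum]:
    """Fold tissue strata with too few MAIT cells into the cancer's tumor stratum."""
    by_cancer: dict[str, list[Stratum]] = {}
    for s in strata:
        by_cancer.setdefault(s.cancer, []).append(s)
    merged: list[Stratum] = []
    for cancer, items in sorted(by_cancer.items()):
        tumor = next((s for s in items if s.tissue == "tumor"), None)
        low = [
            s
            for s in items
            if s.tissue != "tumor" and int((s.subsets == "MAIT").sum()) < min_mait
        ]
        if low and tumor is None:
            raise ConfigError(
                f"cancer {cancer}: low-MAIT stratum but no tumor stratum to merge into"
            )
        keep = [s for s in items if s is not tumor and s not in low]
        if tumor is not None:
            absorbed = [tumor] + low
            if len(absorbed) > 1:
                gene_ids = absorbed[0].matrix.gene_ids
                for s in absorbed[1:]:
                    if s.matrix.gene_ids != gene_ids:
                        raise ConfigError(
                            "cannot merge strata with different gene universes"
                        )
                normexpr = np.concatenate(
                    [s.matrix.normexpr for s in absorbed], axis=1
                )
                cells = sum((list(s.matrix.cell_ids) for s in absorbed), [])
                subsets = np.concatenate([s.subsets for s in absorbed])
                label = "tumor+" + "+".join(s.tissue for s in low)
                tumor = Stratum(
                    cancer=cancer,
                    tissue=label,
                    matrix=GeneExpressionMatrix(
                        gene_ids=list(gene_ids), cell_ids=cells, normexpr=normexpr
                    ),
                    subsets=subsets,
                )
            keep.append(tumor)
        merged.extend(keep)
    return merged


def derive_consensus_signature(
    strata: Sequence[Stratum],
    comparators: Sequence[str] = ("CD8", "CD4", "Treg"),
    config: Optional[DegConfig] = None,
    min_mait_per_stratum: int = 20,
) -> ConsensusResult:
    """Derive the cross-stratum stable MAIT signature.

    Within each (merged) stratum, a gene qualifies iff it is significantly
    higher in MAIT cells than in every comparator subset present
    (BH-adjusted p < 0.1 and fold-change >= 1.5 by default, moderated
    t-tests with trend).  The consensus is the strict intersection of the
    qualifying sets across all strata.
    """
    if config is None:
        config = DegConfig(fc_threshold=1.5, p_adjust_threshold=0.1)
    for s in strata:
        if int((s.subsets == "MAIT").sum()) == 0:
            raise ConfigError(f"stratum ({s.cancer}, {s.tissue}) has no MAIT cells")
    merged = _merge_low_mait_strata(strata, min_mait_per_stratum)
    log_fc_min = np.log2(config.fc_threshold)
    per_stratum: dict = {}
    consensus: Optional[set] = None
    for s in merged:
        present = [c for c in comparators if (s.subsets == c).sum() >= 2]
        if not present:
            raise ConfigError(
                f"stratum ({s.cancer}, {s.tissue}) has no comparator subset"
            )
        use = np.isin(s.subsets, ["MAIT"] + present)
        fit = moderated_fit(
            s.matrix.normexpr[:, use],
            s.subsets[use],
            trend=config.trend,
            gene_ids=s.matrix.gene_ids,
        )
        qualifying: Optional[set] = None
        for comp in present:
            tab = moderated_t_test(fit, ("MAIT", comp))
            hits = set(
                tab.loc[
                    (tab["adj_p"] < config.p_adjust_threshold)
                    & (tab["log2fc"] >= log_fc_min),
                    "gene",
                ]
            )
            qualifying = hits if qualifying is None else (qualifying & hits)
        per_stratum[(s.cancer, s.tissue)] = sorted(qualifying)
        consensus = qualifying if consensus is None else (consensus & qualifying)
    return ConsensusResult(
        genes=sorted(consensus or set()),
        per_stratum=per_stratum,
        n_sets=len(merged),
    )


def marker_specificity_tests(
    matrix: GeneExpressionMatrix,
    signature: SignatureDefinition | Sequence[str],
    subsets: np.ndarray,
    reference: str = "MAIT",
    trend: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-comparator moderated t-tests of signature specificity.

    One row per (signature gene, comparator subset) pair: with 11 genes
    and 6 comparator populations this is the 66-comparison audit of
    whether each marker is elevated in MAIT cells relative to every other
    lymphocyte population.  ``significant`` flags p < 0.05 with a
    positive log2FC toward the reference.
    """
    genes = list(signature.genes if isinstance(signature, SignatureDefinition) else signature)
    subsets = np.asarray(subsets)
    comparators = [g for g in pd.unique(subsets) if g != reference]
    fit = moderated_fit(
        matrix.normexpr, subsets, trend=trend, gene_ids=matrix.gene_ids
    )
    frames = []
    present = [g for g in genes if g in set(matrix.gene_ids)]
    for comp in sorted(map(str, comparators)):
        tab = moderated_t_test(fit, (reference, comp))
        tab = tab[tab["gene"].isin(present)].copy()
        tab["comparator"] = comp
        tab["significant"] = (tab["p"] < 0.05) & (tab["log2fc"] > 0)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["n_comparisons"] = len(out)
    return out
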