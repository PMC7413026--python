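"""Tissue preference (R_O/E), clonotype tissue sharing, and clone dynamics.

R_O/E is the ratio of observed to expected cell counts in a patient's
tissue x subset contingency table, with expected counts from the
chi-square independence model (row total x column total / grand total).
Clone dynamics compare each clonotype's pre- vs post-treatment frequency
with a two-sided Fisher's exact test, BH-corrected within patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import ConfigError
from .stats import bh_adjust
from .tcr import Clonotype

TISSUE_CODE = {"blood": "B", "normal": "N", "tumor": "T"}
COMBINATIONS = ("B", "N", "T", "BN", "BT", "NT", "BNT")


@dataclass
class DistributionTable:
    patient_id: str
    observed: pd.DataFrame  # tissue x subset counts
    expected: pd.DataFrame
    roe: pd.DataFrame


def compute_roe(
    annotations: pd.DataFrame,
    group_by: str = "patient_id",
    subset_col: str = "subset",
    tissue_col: str = "tissue",
) -> list[DistributionTable]:
    """Per-patient R_O/E tables across tissues.

    Patients represented in fewer than two tissues carry no information
    about tissue preference and are excluded with a warning.
    """
    out: list[DistributionTable] = []
    for patient, sub in annotations.groupby(group_by, sort=True):
        observed = pd.crosstab(sub[tissue_col], sub[subset_col])
        if observed.shape[0] < 2:
            warnings.warn(f"patient {patient}: single tissue, excluded from R_O/E")
            continue
        obs = observed.to_numpy(dtype=float)
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        exp_df = pd.DataFrame(expected, index=observed.index, columns=observed.columns)
        out.append(
            DistributionTable(
                patient_id=str(patient),
                observed=observed,
                expected=exp_df,
                roe=observed / exp_df,
            )
        )
    return out


def roe_values(
    tables: Sequence[DistributionTable], subset: str = "MAIT"
) -> pd.DataFrame:
    """Long-format per-patient R_O/E for one subset across tissues."""
    rows = []
    for t in tables:
        if subset not in t.roe.columns:
            continue
        for tissue, value in t.roe[subset].items():
            rows.append({"patient_id": t.patient_id, "tissue": tissue, "roe": value})
    return pd.DataFrame(rows)


def compare_roe(values_a, values_b, welch: bool = True) -> dict:
    """Two-sided unpaired t-test between two groups of per-patient R_O/E."""
    stat, p = scipy.stats.ttest_ind(
        np.asarray(values_a, dtype=float),
        np.asarray(values_b, dtype=float),
        equal_var=not welch,
    )
    return {"t": float(stat), "p": float(p)}


def summarize_sharing(
    clonotypes: Sequence[Clonotype],
    annotations: pd.DataFrame,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Tissue-combination occupancy of clonal clonotypes.

    Each clonal clonotype (size >= 2) is assigned the exact set of tissues
    its member cells occupy, coded B/N/T; non-clonal cells are counted as
    unique clonotypes per single tissue.  Returns one row per
    (group, combination, clonal-status) with clone counts and mean cells
    per clonotype.
    """
    ann = annotations.set_index("cell_id")
    rows = []
    for clone in clonotypes:
        tissues = sorted(
            {TISSUE_CODE[ann.loc[cid, "tissue"]] for cid in clone.member_cell_ids},
            key="BNT".index,
        )
        combo = "".join(tissues)
        group = ann.loc[clone.member_cell_ids[0], group_col] if group_col else "all"
        rows.append(
            {
                "group": group,
                "combination": combo,
                "clonal": clone.clonal,
                "clonotype_id": clone.clonotype_id,
                "size": clone.size,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["group", "combination", "clonal", "n_clonotypes", "mean_cells"]
        )
    summary = (
        df.groupby(["group", "combination", "clonal"])
        .agg(n_clonotypes=("clonotype_id", "size"), mean_cells=("size", "mean"))
        .reset_index()
    )
    return summary


def classify_clone_dynamics(
    clonotypes: Sequence[Clonotype],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    min_cells: int = 10,
    subset: str = "MAIT",
) -> pd.DataFrame:
    """Fate of each clonotype across treatment (pre vs post).

    Patients contribute only if they have at least ``min_cells`` cells of
    the subset in BOTH the pre- and post-treatment samples.  Per clone, a
    two-sided Fisher's exact test compares
    [[pre_count, pre_total-pre_count], [post_count, post_total-post_count]];
    BH adjustment is applied within patient.  Fates: pre_only / post_only
    for clones absent on one side, expanded / depleted for significant
    (q < alpha) proportion increases / decreases, else stable.
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    ann = annotations.set_index("cell_id")
    records = []
    for clone in clonotypes:
        for cid in clone.member_cell_ids:
            row = ann.loc[cid]
            if row["subset"] != subset:
                continue
            records.append(
                {
                    "clonotype_id": clone.clonotype_id,
                    "patient_id": row["patient_id"],
                    "treatment": row["treatment"],
                }
            )
    cells = pd.DataFrame(records)
    out_rows = []
    if cells.empty:
        return pd.DataFrame(
            columns=[
                "patient_id", "clonotype_id", "pre_count", "post_count",
                "pre_total", "post_total", "p_value", "q_value", "fate",
            ]
        )
    for patient, sub in cells.groupby("patient_id", sort=True):
        pre_total = int((sub["treatment"] == "pre").sum())
        post_total = int((sub["treatment"] == "post").sum())
        if pre_total < min_cells or post_total < min_cells:
            continue
        tab = (
            sub.groupby(["clonotype_id", "treatment"]).size().unstack(fill_value=0)
        )
        pre = tab.get("pre", pd.Series(0, index=tab.index))
        post = tab.get("post", pd.Series(0, index=tab.index))
        pvals = []
        for clone_id in tab.index:
            a, b = int(pre[clone_id]), int(post[clone_id])
            table = [[a, pre_total - a], [b, post_total - b]]
            pvals.append(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
        qvals = bh_adjust(pvals)
        for clone_id, p, q in zip(tab.index, pvals, qvals):
            a, b = int(pre[clone_id]), int(post[clone_id])
            if b == 0 and a > 0:
                fate = "pre_only"
            elif a == 0 and b > 0:
                fate = "post_only"
            elif q < alpha and b / post_total > a / pre_total:
                fate = "expanded"
            elif q < alpha and b / post_total < a / pre_total:
                fate = "depleted"
            else:
                fate = "stable"
            out_rows.append(
                {
                    "patient_id": patient,
                    "clonotype_id": clone_id,
                    "pre_count": a,
                    "post_count": b,
                    "pre_total": pre_total,
                    "post_total": post_total,
                    "p_value": p,
                    "q_value": q,
                    "fate": fate,
                }
            )
    return pd.DataFrame(out_rows)
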