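"""Synthetic single-cell and bulk datasets with known ground truth.

The single-cell generator emulates the statistical structure of
multi-patient tumor T-cell atlases: three tissue compartments per
patient, a MAIT subpopulation defined by a planted semi-invariant
TRAV1-2-TRAJ33/12/20 alpha chain, clonal structure with shared and
compartment-private clonotypes (and optional pre/post-treatment
expansion), and planted marker genes elevated in MAIT cells by
configured log2 effects on top of negative-binomial UMI noise.

The bulk generator mixes subset expression profiles with per-sample
Dirichlet fractions, couples MR1 expression to the MAIT fraction, and
draws survival times from a proportional-hazards model with a planted
log-hazard coefficient per standard deviation of the true MAIT
fraction.

Every entry point requires an explicit integer seed and is bit-
reproducible for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .datatypes import BulkCohort, ConfigError, GeneExpressionMatrix
from .genesets import (
    ACTIVATION_GENES,
    EXHAUSTION_GENES,
    MAIT_SIGNATURE_GENES,
    NK_GENES,
    PAN_T_GENES,
)
from .tcr import TcrChain, TcrRecord

_NT = np.array(list("ACGT"))

# Non-MAIT V/J pools: none of these alpha combinations can satisfy the
# TRAV1-2 + TRAJ33/12/20 rule, so ground-truth labels are exact.
_OTHER_TRAV = ("TRAV8-1", "TRAV12-2", "TRAV13-1", "TRAV38-1", "TRAV29")
_OTHER_TRAJ = ("TRAJ10", "TRAJ42", "TRAJ58", "TRAJ49")
_TRBV_POOL = ("TRBV6", "TRBV20", "TRBV19", "TRBV4-2", "TRBV9", "TRBV11-2", "TRBV27", "TRBV28")
_TRBV_WEIGHTS = (0.30, 0.22, 0.12, 0.10, 0.08, 0.07, 0.06, 0.05)
_TRBJ_POOL = ("TRBJ1-1", "TRBJ2-1", "TRBJ2-6", "TRBJ2-7")


@dataclass
class SyntheticScConfig:
    """Study conditions for the synthetic single-cell dataset.

    ``cells_per_subset`` fixes the per-(cancer, tissue) size of each of
    the four T-cell subsets; ``mait_cells_per_tissue`` optionally
    overrides the MAIT count per tissue to plant a tissue preference
    (R_O/E structure).  Planted MAIT markers default to the 11 signature
    symbols with a 1.5 log2 effect; each stratum additionally carries
    stratum-private decoy markers with the same effect, which a
    cross-stratum consensus must reject.  ``lowexpr_markers`` lists
    signature genes forced to near-zero expression everywhere (for
    exercising the low-expression pre-filter).
    """

    seed: int
    cancers: Sequence[str] = ("HCC", "CRC", "NSCLC")
    patients_per_cancer: int = 2
    tissues: Sequence[str] = ("blood", "normal", "tumor")
    cells_per_subset: int = 200
    mait_cells_per_tissue: Optional[Mapping[str, int]] = None
    n_background_genes: int = 800
    markers: Sequence[str] = MAIT_SIGNATURE_GENES
    marker_log2fc: float = 1.5
    n_decoys_per_stratum: int = 2
    decoy_log2fc: float = 1.5
    lowexpr_markers: Sequence[str] = ()
    marker_base_mean: float = 3.0
    activation_log2fc: float = 1.0  # tumor-tissue elevation of activation genes
    exhaustion_log2fc: float = 1.0  # tumor-tissue elevation of exhaustion genes
    nb_dispersion: float = 0.3
    size_factor_sigma: float = 0.3
    traj_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TRAJ33": 0.85, "TRAJ12": 0.10, "TRAJ20": 0.05}
    )
    clone_geometric_p: float = 0.6
    clone_multi_tissue_prob: float = 0.3
    paired_treatment: bool = False
    n_expanded_clones: int = 2
    expansion_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("an explicit integer seed is required")
        if not 0 < self.clone_geometric_p <= 1:
            raise ConfigError("clone_geometric_p must lie in (0, 1]")
        if abs(sum(self.traj_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("traj_probs must sum to 1")
        if self.cells_per_subset < 1:
            raise ConfigError("cells_per_subset must be >= 1")
        n_mait = (
            min(self.mait_cells_per_tissue.values())
            if self.mait_cells_per_tissue
            else self.cells_per_subset
        )
        if n_mait < 1:
            raise ConfigError("the clonal model requires at least one MAIT cell per tissue")


@dataclass
class SyntheticScDataset:
    matrix: GeneExpressionMatrix
    annotations: pd.DataFrame
    records: list[TcrRecord]
    true_markers: list[str]
    decoys: dict  # (cancer, tissue) -> list of decoy gene names
    clone_truth: pd.DataFrame  # cell_id, true_clone, expanded flag


def _random_cdr3(rng: np.random.Generator, length: int = 15) -> str:
    return "".join(rng.choice(_NT, size=length))


def _geometric_sizes(rng: np.random.Generator, total: int, p: float) -> list[int]:
    sizes = []
    remaining = total
    while remaining > 0:
        s = min(int(rng.geometric(p)), remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def _mait_alpha(rng: np.random.Generator, traj_probs: Mapping[str, float]) -> TcrChain:
    j = rng.choice(list(traj_probs), p=list(traj_probs.values()))
    return TcrChain("TRA", "TRAV1-2", str(j), _random_cdr3(rng))


def _clone_beta(rng: np.random.Generator) -> TcrChain:
    v = rng.choice(_TRBV_POOL, p=_TRBV_WEIGHTS)
    return TcrChain("TRB", str(v), str(rng.choice(_TRBJ_POOL)), _random_cdr3(rng))


def _assign_clones_tissue(
    rng: np.random.Generator,
    cells: pd.DataFrame,
    cfg: SyntheticScConfig,
    clone_prefix: str,
) -> pd.Series:
    """Partition one patient's MAIT cells into clones with tissue structure.

    Clone sizes are geometric; each clone draws members either from a
    single tissue or (with probability clone_multi_tissue_prob) from the
    patient's pooled compartments, producing shared and private clones.
    """
    unassigned: dict[str, list[str]] = {
        t: list(cells.loc[cells["tissue"] == t, "cell_id"]) for t in cells["tissue"].unique()
    }
    for ids in unassigned.values():
        rng.shuffle(ids)
    assignment: dict[str, str] = {}
    sizes = _geometric_sizes(rng, len(cells), cfg.clone_geometric_p)
    for k, size in enumerate(sizes):
        pools = {t: ids for t, ids in unassigned.items() if ids}
        if not pools:
            break
        if len(pools) > 1 and rng.random() < cfg.clone_multi_tissue_prob:
            pool = [cid for ids in pools.values() for cid in ids]
        else:
            weights = np.array([len(ids) for ids in pools.values()], dtype=float)
            tissue = list(pools)[rng.choice(len(pools), p=weights / weights.sum())]
            pool = pools[tissue]
        members = pool[: min(size, len(pool))]
        clone_id = f"{clone_prefix}c{k:04d}"
        for cid in members:
            assignment[cid] = clone_id
        for ids in unassigned.values():
            for cid in members:
                if cid in ids:
                    ids.remove(cid)
    # leftovers (when multi-tissue draws exhausted pools unevenly) become singletons
    k = len(sizes)
    for ids in unassigned.values():
        for cid in ids:
            assignment[cid] = f"{clone_prefix}c{k:04d}"
            k += 1
    return pd.Series(assignment)


def _assign_clones_paired(
    rng: np.random.Generator,
    cells: pd.DataFrame,
    cfg: SyntheticScConfig,
    clone_prefix: str,
) -> tuple[pd.Series, list[str]]:
    """Pre/post clone assignment with planted post-treatment expansion."""
    n_pre = int((cells["treatment"] == "pre").sum())
    n_post = int((cells["treatment"] == "post").sum())
    n_clones = max(5, (n_pre + n_post) // 3)
    base = (1.0 - 0.25) ** np.arange(n_clones)
    expanded_idx = list(range(min(cfg.n_expanded_clones, n_clones)))
    w_pre = base / base.sum()
    w_post = base.copy()
    for i in expanded_idx:
        w_post[i] *= cfg.expansion_factor
    w_post = w_post / w_post.sum()
    clone_names = [f"{clone_prefix}c{k:04d}" for k in range(n_clones)]
    assignment: dict[str, str] = {}
    for treat, w in (("pre", w_pre), ("post", w_post)):
        ids = list(cells.loc[cells["treatment"] == treat, "cell_id"])
        draws = rng.choice(n_clones, size=len(ids), p=w)
        for cid, k in zip(ids, draws):
            assignment[cid] = clone_names[k]
    return pd.Series(assignment), [clone_names[i] for i in expanded_idx]


def generate_sc_dataset(config: SyntheticScConfig) -> SyntheticScDataset:
    """Generate expression, annotations, TCR records and ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    treatments = ("pre", "post") if cfg.paired_treatment else ("not_applicable",)

    # --- cell roster ---------------------------------------------------
    rows = []
    idx = 0
    for cancer in cfg.cancers:
        for p in range(1, cfg.patients_per_cancer + 1):
            patient = f"{cancer}_P{p}"
            for tissue in cfg.tissues:
                for treatment in treatments:
                    for subset in ("MAIT", "CD8", "CD4", "Treg"):
                        if subset == "MAIT" and cfg.mait_cells_per_tissue:
                            n = int(cfg.mait_cells_per_tissue[tissue])
                        else:
                            n = cfg.cells_per_subset
                        for _ in range(n):
                            rows.append(
                                {
                                    "cell_id": f"cell{idx:06d}",
                                    "patient_id": patient,
                                    "cancer": cancer,
                                    "tissue": tissue,
                                    "subset": subset,
                                    "treatment": treatment,
                                }
                            )
                            idx += 1
    roster = pd.DataFrame(rows)
    n_cells = len(roster)

    # --- gene universe and baseline means ------------------------------
    markers = list(cfg.markers)
    decoys: dict = {}
    decoy_names: list[str] = []
    for cancer in cfg.cancers:
        for tissue in cfg.tissues:
            names = [
                f"DECOY-{cancer}-{tissue.upper()}-{k + 1}"
                for k in range(cfg.n_decoys_per_stratum)
            ]
            decoys[(cancer, tissue)] = names
            decoy_names.extend(names)
    mito = [f"MT-SYN{k}" for k in range(1, 6)]
    background = [f"GENE{k:05d}" for k in range(1, cfg.n_background_genes + 1)]
    program_genes = [
        g
        for g in list(ACTIVATION_GENES) + list(EXHAUSTION_GENES)
        if g not in markers
    ]
    gene_ids = markers + list(PAN_T_GENES) + program_genes + decoy_names + mito + background
    n_genes = len(gene_ids)

    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))  # mean UMI per cell
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for g in markers + decoy_names + program_genes:
        base[gpos[g]] = cfg.marker_base_mean
    for g in PAN_T_GENES:
        base[gpos[g]] = 2.0 * cfg.marker_base_mean
    for g in mito:
        base[gpos[g]] = 1.0
    for g in cfg.lowexpr_markers:
        base[gpos[g]] = 0.002  # detected in <1% of cells

    # --- planted effects ------------------------------------------------
    mu = base[:, None] * np.exp(
        rng.normal(0.0, cfg.size_factor_sigma, size=n_cells)
    )[None, :]
    is_mait = (roster["subset"] == "MAIT").to_numpy()
    marker_rows = np.array([gpos[g] for g in markers])
    mu[np.ix_(marker_rows, is_mait)] *= 2.0 ** cfg.marker_log2fc
    for (cancer, tissue), names in decoys.items():
        mask = (
            is_mait
            & (roster["cancer"] == cancer).to_numpy()
            & (roster["tissue"] == tissue).to_numpy()
        )
        drows = np.array([gpos[g] for g in names])
        mu[np.ix_(drows, mask)] *= 2.0 ** cfg.decoy_log2fc
    # activation/exhaustion programs up-regulated in tumor-infiltrating T cells
    in_tumor = (roster["tissue"] == "tumor").to_numpy()
    if in_tumor.any():
        act_rows = np.array([gpos[g] for g in ACTIVATION_GENES if g in gpos])
        exh_rows = np.array([gpos[g] for g in EXHAUSTION_GENES if g in gpos])
        mu[np.ix_(act_rows, in_tumor)] *= 2.0 ** cfg.activation_log2fc
        mu[np.ix_(exh_rows, in_tumor)] *= 2.0 ** cfg.exhaustion_log2fc

    # --- negative-binomial counts (gamma-Poisson) -----------------------
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu * cfg.nb_dispersion)
    counts = rng.poisson(lam).astype(float)

    matrix = GeneExpressionMatrix(
        gene_ids=gene_ids, cell_ids=list(roster["cell_id"]), counts=counts
    )

    # --- TCR records and clonal structure -------------------------------
    clone_of: dict[str, str] = {}
    expanded_clones: list[str] = []
    for patient, sub in roster[roster["subset"] == "MAIT"].groupby("patient_id", sort=True):
        prefix = f"{patient}_"
        if cfg.paired_treatment:
            assign, expanded = _assign_clones_paired(rng, sub, cfg, prefix)
            expanded_clones.extend(expanded)
        else:
            assign = _assign_clones_tissue(rng, sub, cfg, prefix)
        clone_of.update(assign.to_dict())

    clone_chains: dict[str, tuple[TcrChain, TcrChain]] = {}
    records: list[TcrRecord] = []
    for row in roster.itertuples(index=False):
        if row.subset == "MAIT":
            clone = clone_of[row.cell_id]
            if clone not in clone_chains:
                clone_chains[clone] = (
                    _mait_alpha(rng, cfg.traj_probs),
                    _clone_beta(rng),
                )
            alpha, beta = clone_chains[clone]
        else:
            alpha = TcrChain(
                "TRA",
                str(rng.choice(_OTHER_TRAV)),
                str(rng.choice(_OTHER_TRAJ)),
                _random_cdr3(rng),
            )
            beta = _clone_beta(rng)
        records.append(TcrRecord(cell_id=row.cell_id, chains=[alpha, beta]))

    annotations = roster[
        ["cell_id", "patient_id", "tissue", "subset", "treatment"]
    ].copy()
    clone_truth = roster[["cell_id", "subset"]].copy()
    clone_truth["true_clone"] = clone_truth["cell_id"].map(clone_of)
    clone_truth["expanded"] = clone_truth["true_clone"].isin(expanded_clones)
    return SyntheticScDataset(
        matrix=matrix,
        annotations=annotations,
        records=records,
        true_markers=[m for m in markers if m not in cfg.lowexpr_markers],
        decoys=decoys,
        clone_truth=clone_truth,
    )


def stratify_for_consensus(dataset: SyntheticScDataset):
    """Split a synthetic dataset into (cancer, tissue) strata with normexpr."""
    from .qc import add_normexpr
    from .signatures import Stratum

    ann = dataset.annotations.copy()
    cancer = ann["patient_id"].str.split("_").str[0]
    strata = []
    for (cn, tissue), sub in ann.groupby([cancer, "tissue"], sort=True):
        idx = dataset.matrix.cell_ids
        mask = pd.Series(False, index=idx)
        mask.loc[sub["cell_id"]] = True
        m = add_normexpr(dataset.matrix.subset_cells(mask.to_numpy()))
        subs = sub.set_index("cell_id").loc[m.cell_ids, "subset"].to_numpy()
        strata.append(Stratum(cancer=cn, tissue=tissue, matrix=m, subsets=subs))
    return strata


# ----------------------------------------------------------------------
# Bulk cohorts
# ----------------------------------------------------------------------

@dataclass
class SyntheticBulkConfig:
    """Study conditions for the synthetic bulk cohort.

    Composition is hierarchical, mimicking immune-hot vs immune-cold
    tumors: the total T-cell fraction of each sample is Beta-distributed
    (wide), and within-T shares follow a Dirichlet over the four T
    subsets with MAIT the smallest.  Expression is the fraction-weighted
    mixture of subset profiles on the TPM scale plus log-normal noise on
    log2(TPM+1).  Survival follows an exponential baseline with hazard
    h0 * exp(beta * z) where z is the standardized true MAIT fraction;
    censoring is independent exponential, calibrated so the expected
    censored fraction matches ``censoring``.
    """

    seed: int
    n_samples: int = 600
    t_fraction_beta: tuple[float, float] = (2.0, 3.0)
    dirichlet_alpha: Mapping[str, float] = field(
        default_factory=lambda: {
            "MAIT": 0.8,
            "CD8": 4.0,
            "CD4": 4.0,
            "Treg": 2.0,
        }
    )
    n_background_genes: int = 200
    marker_profile_log2fc: float = 3.0
    log_noise_sigma: float = 0.5
    baseline_hazard: float = 1.0 / 1000.0  # per day
    log_hr_per_sd: float = 0.5
    censoring: float = 0.30
    mr1_coupling: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("an explicit integer seed is required")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if not 0 <= self.censoring < 1:
            raise ConfigError("censoring must lie in [0, 1)")


@dataclass
class SyntheticBulkDataset:
    cohort: BulkCohort
    fractions: pd.DataFrame  # sample x subset true fractions
    z_mait: np.ndarray  # standardized true MAIT fraction (the hazard covariate)


def simulate_survival(
    z: np.ndarray,
    beta: float,
    baseline_hazard: float,
    censoring: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) from h(t) = h0 * exp(beta * z) with independent
    exponential censoring calibrated to the target censored fraction."""
    z = np.asarray(z, dtype=float)
    rates = baseline_hazard * np.exp(beta * z)
    event_times = rng.exponential(1.0 / rates)
    if censoring <= 0:
        return event_times, np.ones_like(event_times)

    def expected_censored(mu: float) -> float:
        return float(np.mean(mu / (rates + mu))) - censoring

    lo, hi = 1e-12, 1e6 * baseline_hazard
    while expected_censored(hi) < 0:
        hi *= 10
    mu = scipy.optimize.brentq(expected_censored, lo, hi)
    censor_times = rng.exponential(1.0 / mu, size=z.size)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(float)
    return times, events


def generate_bulk_cohort(config: SyntheticBulkConfig) -> SyntheticBulkDataset:
    """Generate a sample x gene log2(TPM+1) cohort with survival endpoints."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    subsets = list(cfg.dirichlet_alpha) + ["other"]
    genes = (
        list(MAIT_SIGNATURE_GENES)
        + list(PAN_T_GENES)
        + list(NK_GENES)
        + ["MR1"]
        + [f"GENE{k:05d}" for k in range(1, cfg.n_background_genes + 1)]
    )
    gpos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base = np.exp(rng.normal(3.0, 1.0, size=n_genes))  # shared TPM-scale baseline
    profiles = np.tile(base, (len(subsets), 1))
    boost = 2.0 ** cfg.marker_profile_log2fc
    for g in MAIT_SIGNATURE_GENES:
        profiles[subsets.index("MAIT"), gpos[g]] *= boost
    for g in PAN_T_GENES:
        for s in ("MAIT", "CD8", "CD4", "Treg"):
            profiles[subsets.index(s), gpos[g]] *= boost
    for g in NK_GENES:
        profiles[subsets.index("other"), gpos[g]] *= boost / 2.0

    t_frac = rng.beta(*cfg.t_fraction_beta, size=cfg.n_samples)
    shares = rng.dirichlet(list(cfg.dirichlet_alpha.values()), size=cfg.n_samples)
    fractions = np.column_stack([shares * t_frac[:, None], 1.0 - t_frac])
    mix = fractions @ profiles  # samples x genes, linear scale
    mix = mix / mix.sum(axis=1, keepdims=True) * 1e6  # TPM
    expr = np.log2(mix + 1.0) + rng.normal(0.0, cfg.log_noise_sigma, size=mix.shape)

    frac_mait = fractions[:, subsets.index("MAIT")]
    z = (frac_mait - frac_mait.mean()) / frac_mait.std(ddof=1)
    expr[:, gpos["MR1"]] = (
        np.log2(base[gpos["MR1"]] + 1.0)
        + cfg.mr1_coupling * z
        + rng.normal(0.0, 0.3, size=cfg.n_samples)
    )

    sample_ids = [f"S{k:04d}" for k in range(cfg.n_samples)]
    os_time, os_event = simulate_survival(
        z, cfg.log_hr_per_sd, cfg.baseline_hazard, cfg.censoring, rng
    )
    pfs_time, pfs_event = simulate_survival(
        z, cfg.log_hr_per_sd, cfg.baseline_hazard * 1.5, cfg.censoring, rng
    )
    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
        },
        index=sample_ids,
    )
    cohort = BulkCohort(
        expr=pd.DataFrame(expr, index=sample_ids, columns=genes), clinical=clinical
    )
    return SyntheticBulkDataset(
        cohort=cohort,
        fractions=pd.DataFrame(fractions, index=sample_ids, columns=subsets),
        z_mait=z,
    )
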