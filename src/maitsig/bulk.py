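"""Bulk-cohort signature validation, trimming, scoring and survival models.

Within each bulk cohort the 11 MAIT signature genes are audited against
pan-T and NK markers with Kendall's tau-b (tie-robust rank correlation).
Three trimming rules retain only genes whose expression is coupled with
the MAIT/T-cell axis: a gene must (1) correlate positively and
significantly with the anchor gene SLC4A10, (2) correlate with all, or
all but one, of the other retained signature genes, and (3) correlate
with at least two pan-T markers.  Rule (2) references the retained set
itself, so the rules are iterated to a fixed point by repeatedly
removing the worst violator.  Cohorts keeping >= 5 genes are eligible
for survival analysis: samples are stratified at the 33rd/67th score
percentiles and a univariate Cox proportional-hazards model (Efron
ties) contrasts the high vs low tertile, alongside Kaplan-Meier curves
and a log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .datatypes import BulkCohort, ConfigError, StructuralError
from .genesets import MAIT_SIGNATURE_GENES, PAN_T_GENES


@dataclass
class CorrelationReport:
    markers: list[str]
    tau: pd.DataFrame  # symmetric, diagonal 1
    p: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    def significant_positive(self, a: str, b: str, alpha: float = 0.05) -> bool:
        """Rule predicate: tau > 0 with two-sided p < alpha."""
        return bool(self.tau.loc[a, b] > 0 and self.p.loc[a, b] < alpha)


def kendall_matrix(
    cohort: BulkCohort, markers: Sequence[str]
) -> CorrelationReport:
    """Pairwise Kendall tau-b among marker genes in a bulk cohort.

    Missing markers are dropped with a warning; constant genes get
    tau = 0 (flagged) since rank correlation is undefined for them.
    """
    if len(cohort.sample_ids) < 10:
        raise ConfigError("kendall_matrix requires >= 10 samples")
    present = [m for m in markers if m in cohort.expr.columns]
    absent = sorted(set(markers) - set(present))
    if absent:
        warnings.warn(f"markers absent from cohort, dropped: {absent}")
    if len(present) < 2:
        raise ConfigError("fewer than 2 marker genes present in cohort")
    x = cohort.expr.loc[:, present].to_numpy(dtype=float)
    constant = [g for j, g in enumerate(present) if np.all(x[:, j] == x[0, j])]
    m = len(present)
    tau = np.eye(m)
    pmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if present[i] in constant or present[j] in constant:
                t, p = 0.0, 1.0
            else:
                res = scipy.stats.kendalltau(x[:, i], x[:, j])
                t, p = float(res.statistic), float(res.pvalue)
            tau[i, j] = tau[j, i] = t
            pmat[i, j] = pmat[j, i] = p
    return CorrelationReport(
        markers=present,
        tau=pd.DataFrame(tau, index=present, columns=present),
        p=pd.DataFrame(pmat, index=present, columns=present),
        constant_genes=constant,
    )


@dataclass
class TrimmedSignature:
    cancer: str
    retained: list[str]
    removed: dict  # gene -> list of violated rule labels at removal time
    eligible: bool


def _rule_violations(
    gene: str,
    retained: Sequence[str],
    report: CorrelationReport,
    anchor: str,
    pan_t: Sequence[str],
    alpha: float,
) -> list[str]:
    violations = []
    if gene != anchor and not report.significant_positive(gene, anchor, alpha):
        violations.append("rule1_anchor")
    others = [g for g in retained if g != gene]
    n_corr = sum(report.significant_positive(gene, g, alpha) for g in others)
    if others and n_corr < len(others) - 1:
        violations.append("rule2_mutual")
    pan_present = [g for g in pan_t if g in report.markers]
    n_pan = sum(report.significant_positive(gene, g, alpha) for g in pan_present)
    if n_pan < 2:
        violations.append("rule3_pan_t")
    return violations


def trim_signature(
    report: CorrelationReport,
    cancer: str = "cohort",
    signature: Sequence[str] = MAIT_SIGNATURE_GENES,
    anchor: str = "SLC4A10",
    pan_t_genes: Sequence[str] = PAN_T_GENES,
    alpha: float = 0.05,
    min_genes: int = 5,
) -> TrimmedSignature:
    """Iterate the three trimming rules to a fixed point.

    At each step every retained gene is checked against the CURRENT
    retained set; if any gene violates a rule, the worst violator (most
    violations, ties broken by smallest tau with the anchor, then by
    gene name) is removed and the rules re-evaluated.  The anchor is
    exempt from rule (1).  Terminates in at most len(signature) steps.
    """
    if anchor not in report.markers:
        raise ConfigError(f"anchor gene '{anchor}' missing from correlation report")
    retained = [g for g in signature if g in report.markers]
    removed: dict = {g: ["absent_from_cohort"] for g in signature if g not in report.markers}
    while True:
        violations = {
            g: _rule_violations(g, retained, report, anchor, pan_t_genes, alpha)
            for g in retained
        }
        violators = {g: v for g, v in violations.items() if v}
        if not violators:
            break
        worst = sorted(
            violators,
            key=lambda g: (-len(violators[g]), report.tau.loc[g, anchor], g),
        )[0]
        removed[worst] = violators[worst]
        retained = [g for g in retained if g != worst]
        if not retained:
            break
    return TrimmedSignature(
        cancer=cancer,
        retained=retained,
        removed=removed,
        eligible=len(retained) >= min_genes,
    )


@dataclass
class BulkScores:
    sample_ids: list[str]
    mait_score: np.ndarray
    t_score: np.ndarray
    residual_score: np.ndarray
    residualized: bool  # False when the T score was constant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "mait_score": self.mait_score,
                "t_score": self.t_score,
                "residual_score": self.residual_score,
            }
        )


def _zscore_mean(expr: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    sub = expr.loc[:, list(genes)].to_numpy(dtype=float)
    mean = sub.mean(axis=0, keepdims=True)
    sd = sub.std(axis=0, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (sub - mean) / sd, 0.0)
    return z.mean(axis=1)


def score_bulk(
    cohort: BulkCohort,
    trimmed: TrimmedSignature | Sequence[str],
    pan_t_genes: Sequence[str] = PAN_T_GENES,
) -> BulkScores:
    """Per-sample MAIT score, T score, and T-cell-adjusted residual score.

    Both scores are means of per-gene z-scores over samples.  The
    residual score removes overall T-cell infiltration by ordinary
    least-squares regression of the MAIT score on the T score
    (intercept included), keeping the residuals.
    """
    genes = trimmed.retained if isinstance(trimmed, TrimmedSignature) else list(trimmed)
    if isinstance(trimmed, TrimmedSignature) and not trimmed.eligible:
        raise ConfigError(
            f"trimmed signature for {trimmed.cancer} is not eligible (<5 genes)"
        )
    missing = [g for g in genes if g not in cohort.expr.columns]
    if missing:
        raise StructuralError(f"signature genes missing from cohort: {missing}")
    pan_present = [g for g in pan_t_genes if g in cohort.expr.columns]
    if not pan_present:
        raise StructuralError("no pan-T gene present in cohort")
    mait = _zscore_mean(cohort.expr, genes)
    tsc = _zscore_mean(cohort.expr, pan_present)
    if np.std(tsc) == 0:
        warnings.warn("T score is constant; residualization skipped")
        return BulkScores(cohort.sample_ids, mait, tsc, mait.copy(), residualized=False)
    slope, intercept = np.polyfit(tsc, mait, 1)
    residual = mait - (intercept + slope * tsc)
    return BulkScores(cohort.sample_ids, mait, tsc, residual, residualized=True)


@dataclass
class SurvivalModelResult:
    cancer: str
    endpoint: str  # OS or PFS
    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_p: float
    group_sizes: dict  # low / middle / high
    unstable: bool = False
    km_curves: Optional[dict] = None


def tertile_groups(scores: np.ndarray) -> np.ndarray:
    """Assign low/middle/high by the 33rd and 67th percentiles.

    Percentiles use the linear-interpolation definition; samples exactly
    on a boundary go to the lower stratum.
    """
    q33, q67 = np.percentile(scores, [33, 67])
    groups = np.where(scores <= q33, "low", np.where(scores <= q67, "middle", "high"))
    return groups


def survival_test(
    scores: np.ndarray,
    cohort: BulkCohort,
    endpoint: str = "OS",
    cancer: str = "cohort",
    mode: str = "tertile",
) -> SurvivalModelResult:
    """Univariate Cox PH test of a score against a survival endpoint.

    ``tertile`` mode (default) stratifies at the 33rd/67th percentiles and
    contrasts high vs low (middle excluded from the hazard-ratio fit);
    ``continuous`` mode fits the standardized score directly on all
    samples.  Kaplan-Meier curves and the log-rank test always compare
    the high and low tertiles.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("OS", "PFS"):
        raise ConfigError("endpoint must be OS or PFS")
    tcol, ecol = (f"{endpoint.lower()}_time", f"{endpoint.lower()}_event")
    times = cohort.clinical[tcol].to_numpy(dtype=float)
    events = cohort.clinical[ecol].to_numpy(dtype=float)
    ok = np.isfinite(times) & np.isfinite(events)
    if ok.sum() < 30:
        raise ConfigError(f"fewer than 30 samples with non-missing {endpoint} data")
    scores = np.asarray(scores, dtype=float)[ok]
    times, events = times[ok], events[ok]

    groups = tertile_groups(scores)
    sizes = {g: int((groups == g).sum()) for g in ("low", "middle", "high")}
    lo, hi = groups == "low", groups == "high"
    unstable = events[lo].sum() == 0 or events[hi].sum() == 0
    if unstable:
        warnings.warn("a tertile stratum has zero events; HR is unstable")

    if mode == "tertile":
        mask = lo | hi
        df = pd.DataFrame(
            {
                "time": times[mask],
                "event": events[mask],
                "x": (groups[mask] == "high").astype(float),
            }
        )
    elif mode == "continuous":
        sd = scores.std(ddof=1)
        df = pd.DataFrame(
            {"time": times, "event": events, "x": (scores - scores.mean()) / sd}
        )
    else:
        raise ConfigError("mode must be 'tertile' or 'continuous'")

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_
    ci_low = float(np.exp(ci.iloc[0, 0]))
    ci_high = float(np.exp(ci.iloc[0, 1]))
    wald_p = float(cph.summary.loc["x", "p"])

    lr = logrank_test(times[lo], times[hi], events[lo], events[hi])
    km: dict = {}
    for label, mask in (("low", lo), ("high", hi)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=label)
        km[label] = kmf.survival_function_

    return SurvivalModelResult(
        cancer=cancer,
        endpoint=endpoint,
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        wald_p=wald_p,
        logrank_p=float(lr.p_value),
        group_sizes=sizes,
        unstable=bool(unstable),
        km_curves=km,
    )


def mr1_association(cohort: BulkCohort, scores: np.ndarray) -> dict:
    """Pearson correlation between MR1 expression and the residual MAIT score."""
    if "MR1" not in cohort.expr.columns:
        raise StructuralError("MR1 is absent from the cohort expression matrix")
    mr1 = cohort.expr["MR1"].to_numpy(dtype=float)
    r, p = scipy.stats.pearsonr(mr1, np.asarray(scores, dtype=float))
    return {"r": float(r), "p": float(p), "n": int(len(mr1))}
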