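#!/usr/bin/env python
"""Bulk-cohort prognostic analysis of the MAIT signature.

On the synthetic bulk cohort: Kendall-tau marker correlation audit,
rule-based signature trimming, residual (T-cell-adjusted) MAIT scoring,
MR1 association, and tertile-stratified Cox / Kaplan-Meier survival
models for OS and PFS.
"""

import importlib.util
import json
from pathlib import Path

import numpy as np
import pandas as pd

import maitsig as m
from maitsig.io import ensure_dir

spec = importlib.util.spec_from_file_location(
    "sim", Path(__file__).parent / "01_simulate_cohorts.py"
)
sim = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim)


def main() -> None:
    out = ensure_dir("results")
    ds = m.generate_bulk_cohort(sim.BULK_CFG)
    panel = list(m.MAIT_SIGNATURE_GENES) + list(m.PAN_T_GENES) + list(m.NK_GENES)

    rep = m.kendall_matrix(ds.cohort, panel)
    rep.tau.round(4).to_csv(f"{out}/05_kendall_tau.tsv", sep="\t")

    trimmed = m.trim_signature(rep)
    with open(f"{out}/05_trim_decisions.json", "w") as fh:
        json.dump(
            {"retained": trimmed.retained, "removed": trimmed.removed,
             "eligible": trimmed.eligible},
            fh, indent=2,
        )
    print(f"trimming retained {len(trimmed.retained)}/11 genes "
          f"(eligible: {trimmed.eligible}); removed: {sorted(trimmed.removed)}")

    scores = m.score_bulk(ds.cohort, trimmed)
    print(f"residual score orthogonal to T score: "
          f"r = {np.corrcoef(scores.residual_score, scores.t_score)[0, 1]:.1e}")
    mr1 = m.mr1_association(ds.cohort, scores.residual_score)
    print(f"MR1 vs residual MAIT score: r = {mr1['r']:.3f}, p = {mr1['p']:.2e}")

    rows = []
    for endpoint in ("OS", "PFS"):
        res = m.survival_test(scores.residual_score, ds.cohort, endpoint)
        rows.append(
            {
                "endpoint": endpoint,
                "hazard_ratio": res.hazard_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "wald_p": res.wald_p,
                "logrank_p": res.logrank_p,
                **{f"n_{k}": v for k, v in res.group_sizes.items()},
            }
        )
        print(f"{endpoint}: high-vs-low tertile HR = {res.hazard_ratio:.2f} "
              f"[{res.ci_low:.2f}, {res.ci_high:.2f}], "
              f"log-rank p = {res.logrank_p:.2e}")
    pd.DataFrame(rows).to_csv(f"{out}/05_survival_models.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
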