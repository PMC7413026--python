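# maitsig

Analysis pipeline for **mucosa-associated invariant T (MAIT) cells** in
single-cell TCR + expression data and bulk tumor cohorts.

MAIT cells are innate-like T cells defined by a semi-invariant TCRα
chain (TRAV1-2 joined to TRAJ33/12/20) restricted by MR1. Because the
defining feature is a TCR rearrangement rather than a transcriptional
cluster, they can be identified exactly in single-cell data with paired
TCR sequencing — and only approximately, via a gene signature, in bulk
expression data. This package implements both ends of that problem and
the validation bridging them:

* **TCR repertoire** — classify MAIT cells from contigs, build
  clonotypes (exact α–β pair, or shared-chain for droplet data),
  summarize TRAJ/TRBV segment usage.
* **Tissue distribution and clonal dynamics** — R\_O/E (observed /
  expected cell counts under the chi-square independence model),
  clonotype sharing across blood/normal/tumor compartments, and
  pre-/post-treatment clone fates by Fisher's exact test with
  within-patient BH correction.
* **Moderated differential expression** — an empirical-Bayes moderated
  one-way model (limma-trend style: per-gene variances shrunk toward a
  mean-expression-dependent prior estimated by moment matching on
  log-variances), with a hierarchical F-screen → pairwise-t procedure.
* **Signatures** — per-cell module scores (mean of per-gene z-scores)
  for activation, exhaustion and the 11-gene MAIT signature
  (*SLC4A10, KLRB1, ME1, TMIGD2, IL23R, NCR3, LST1, COLQ, RORC,
  ZBTB16, TLE1*), and consensus signature derivation as the strict
  intersection of MAIT-vs-every-subset DEG sets across cancer × tissue
  strata.
* **Pseudo-bulk validation** — sum UMI counts of n cells sampled
  without replacement, score the mixture, and correlate the score with
  the known MAIT fraction (MAD-based outlier removal, Pearson r).
* **Bulk prognostics** — Kendall τ_b marker-correlation audit,
  rule-based per-cohort signature trimming (≥ 5 genes retained for
  eligibility), T-cell-adjusted residual MAIT scores, MR1 association,
  and tertile-stratified Cox proportional-hazards / Kaplan-Meier
  survival models.
* **Synthetic data** — generators for single-cell atlases (planted
  markers, planted semi-invariant TCRs, clonal structure, pre/post
  expansion) and bulk cohorts (mixture expression, planted hazard
  link), so every stage is testable end-to-end with known ground truth.

## Worked example

```python
import maitsig as m

# a synthetic 3-cancer atlas with 11 planted MAIT markers (log2FC 1.5)
ds = m.generate_sc_dataset(m.SyntheticScConfig(seed=1, cells_per_subset=200))

# TCR-based classification recovers the planted labels exactly
flags = m.classify_mait(ds.records)
truth = ds.annotations.set_index("cell_id")["subset"] == "MAIT"
print((flags.set_index("cell_id")["is_mait"] == truth).mean())   # 1.0

# consensus signature across 3 cancers x 3 tissues
res = m.derive_consensus_signature(m.stratify_for_consensus(ds))
print(res.n_sets, sorted(res.genes))
# 9 ['COLQ', 'IL23R', 'KLRB1', 'LST1', 'ME1', 'NCR3', 'RORC',
#    'SLC4A10', 'TLE1', 'TMIGD2', 'ZBTB16']
```

The nine intersected DEG sets (three tissues × three cancers) recover
exactly the eleven planted signature genes: sensitivity and precision
are both 1.0 against the generator's ground truth.

The numbered scripts under `analysis/` run the full narrative and
write small summary tables to `results/`:

```bash
python analysis/01_simulate_cohorts.py       # the three study cohorts
python analysis/02_repertoire_and_clonality.py
python analysis/03_expression_and_signature.py
python analysis/04_pseudobulk_validation.py
python analysis/05_bulk_prognostics.py
```

Representative output (seeds fixed in the scripts): MAIT R\_O/E of
0.68 / 1.54 / 0.59 in blood / normal / tumor for the planted
normal-tissue enrichment; pseudo-bulk r(MAIT score, MAIT fraction) =
0.93 at n = 3,000 cells; bulk trimming retains 6/11 genes (eligible);
high-vs-low tertile hazard ratio ≈ 2.0 for the planted 0.5 log-hazard
per SD; MR1–score correlation r ≈ 0.60.

## Layout

```
src/maitsig/       library (data model, IO, QC, TCR, clonal, diffexpr,
                   signatures, pseudobulk, bulk prognostics, synthetic data)
analysis/          numbered narrative drivers writing results/
tests/             pytest suite incl. brute-force oracles and
                   end-to-end acceptance checks
docs/methods.md    models, defaults, numerical conventions, limitations
```
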