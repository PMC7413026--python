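# Methods

`maitsig` re-implements, as a tested pipeline, a set of computational
procedures for studying mucosa-associated invariant T (MAIT) cells in
single-cell TCR + expression data and for estimating and validating
MAIT abundance in bulk tumor cohorts. This note documents the models,
the defaults and why they were chosen, what the synthetic data do and
do not emulate, and the numerical conventions.

## MAIT classification and clonotypes

A cell is analysis-eligible when at least one productive TRA and one
productive TRB contig were assembled. A cell is called MAIT iff any
productive TRA chain uses TRAV1-2 joined to TRAJ33, TRAJ12 or TRAJ20 —
the semi-invariant alpha chain that defines the lineage (MR1-restricted).
Allele suffixes (`*01`) are stripped before matching because contig
annotators differ in allele reporting. Cells with several productive
alpha chains count as MAIT if any chain matches; requiring the dominant
chain is not possible without UMI-level chain abundances.

Clonotypes come in two flavors. `exact_pair` groups cells by an
identical (V, J, CDR3nt) alpha-beta pair, with the lexicographically
smallest productive chain per locus as a deterministic tie-break for
multi-chain cells. `shared_chain` merges cells that share at least one
productive alpha and one productive beta nucleotide sequence, taking
the transitive closure with a union-find — the right convention for
droplet data, where chain recovery is incomplete. Every exact-pair
clone is contained in a single shared-chain clone, and both partitions
cover exactly the eligible cells.

## Tissue preference and clonal dynamics

Tissue preference is quantified as R_O/E, the ratio of observed to
expected cell counts in a per-patient tissue x subset contingency
table, with expected counts from the chi-square independence model
(row total x column total / grand total). Patients sampled in fewer
than two tissues carry no information and are excluded. Cross-group
comparisons of per-patient R_O/E use a two-sided unpaired t-test with
Welch correction on by default (no variance-homogeneity assumption is
warranted for handfuls of patients).

Clone dynamics across treatment compare, per clonotype, the 2x2 table
[[pre_count, pre_total - pre_count], [post_count, post_total -
post_count]] with a two-sided Fisher exact test (probability-mass
definition of two-sidedness, matching mainstream implementations).
Patients enter only with >= 10 MAIT cells in both the pre- and
post-treatment samples; p-values are BH-adjusted within patient at
q < 0.05 — no correction is canonical for clone-level tests, and
within-patient BH is the conservative choice consistent with the rest
of the pipeline. Fates: `pre_only`/`post_only` for clones absent on one
side, `expanded`/`depleted` for significant proportion shifts, else
`stable`.

## Moderated differential expression

Expression tests use an empirical-Bayes moderated one-way linear model
on log2-scale expression. Per gene the residual variance s2_g on
d = N - k degrees of freedom is shrunk toward a prior s0^2 via the
scaled-F model s2_g ~ s0^2 F(d, d0). The prior parameters are
estimated by closed-form moment matching on log s2_g using
digamma/trigamma identities (trigamma inverted by Newton iteration);
with `trend=True` the prior location is a lowess curve (span 0.5) over
average log2 expression, so low-expression genes are shrunk toward
their own, larger, prior variance. The posterior variance
(d0 s0^2 + d s2_g) / (d0 + d) feeds moderated t and F statistics on
d0 + d degrees of freedom. Degenerate cases: d0 = 0 reproduces
ordinary statistics exactly; d0 = inf pins all variances at s0^2;
zero-variance genes take the prior variance (t = 0 when means also
tie), avoiding division by zero without discarding genes.

The hierarchical procedure screens genes with the moderated F across
all groups (BH-adjusted p < 0.2) and reports pairwise moderated
t-tests only for the survivors. Stage-2 BH spans the *full* gene set:
re-computing BH within the survivor set leaves the selected (extreme)
genes essentially uncorrected — in global-null simulations roughly a
quarter of replicates produced a false call that way, versus the
nominal 5% — so survivor-set adjustment was rejected. Significance
requires both the adjusted p below threshold and |mean log2
difference| >= log2(fold-change threshold): 1.5 for tissue contrasts,
1.25 for checkpoint-therapy contrasts, with p < 0.1 for marker
derivation. The fold-change applies on the log2 scale (ratio of
geometric means), the convention of moderated-model pipelines.

## Module scores and the consensus signature

A module score is the per-cell mean of per-gene z-scores of log2
expression (sample SD, constant genes contribute zero). The score is
invariant to any per-gene positive affine transform. Score
comparisons between two cell groups use the Wilcoxon rank-sum test —
exact enumeration for tie-free groups of <= 25, tie-corrected normal
approximation otherwise. (The unpaired design admits no signed-rank
pairing.)

The consensus MAIT signature intersects, across cancer x tissue
strata, the genes significantly higher in MAIT cells than in *every*
comparator subset (CD8, CD4, Treg) within the stratum (adjusted
p < 0.1, fold-change >= 1.5, moderated t with trend). Strata with
fewer than 20 MAIT cells are merged into the same cancer's tumor
stratum before testing — generalizing the handling of a 15-cell
normal-tissue stratum — so the number of intersected sets is the
post-merge stratum count (9 for three cancers x three tissues with no
merging). Genes absent from a stratum cannot qualify there; the
intersection is strict, so adding strata can only shrink the set.

## Pseudo-bulk validation

Pseudo-bulk samples sum raw UMI counts of n cells drawn without
replacement from the annotated pool (samples are independent and may
overlap). Normalization is log2(1e6 * count / library_size + 1).
The sample-level MAIT score is the plain mean of the signature genes'
normalized expression — deliberately not z-scored, since in a
deployment setting the score must be computable per sample;
a z-scored variant (across samples) is exposed as an option.
Signature genes detected in < 1% of cells are pre-filtered (the
threshold is configurable; removal of lowly expressed genes is the
stated practice, without a printed cutoff). Before correlating score
with the true MAIT fraction, samples whose score lies beyond three
*raw* median absolute deviations of the median are removed once (no
1.4826 consistency factor — none is stated), and all four subset
correlations are computed on the surviving samples.

## Bulk scoring, trimming and survival

Within a bulk cohort the signature is audited with Kendall's tau-b
(tie-corrected) between all pairs of signature, pan-T (CD3D/E/G) and
NK marker genes. "Significantly correlated" means tau > 0 with
two-sided p < 0.05; the validation narrative concerns positive
coupling, so a negative correlation never counts. Trimming retains
genes that (1) correlate with the anchor SLC4A10 (anchor exempt),
(2) correlate with all or all-but-one of the currently retained
signature genes, and (3) correlate with at least two pan-T markers.
Because rule (2) is self-referential, the rules are iterated to a
fixed point by removing the worst violator (most violations; ties
broken by smallest tau with the anchor, then gene name) — this
terminates in at most 11 steps and re-running changes nothing.
Cohorts retaining >= 5 genes are eligible for survival analysis.

The per-sample MAIT score and T score are means of per-gene z-scores
over samples; the residual MAIT score is the residual of an OLS
regression (with intercept) of MAIT score on T score, removing overall
T-cell infiltration and exactly orthogonal to it. Survival models
stratify samples at the 33rd/67th score percentiles
(linear-interpolation quantiles; boundary values go to the lower
stratum) and fit a univariate Cox proportional-hazards model (Efron
ties, via lifelines) contrasting high vs low with the middle tertile
excluded; a continuous-score mode (standardized predictor on all
samples) is exposed as an option and is what parameter-recovery
simulations use. Kaplan-Meier curves and the log-rank test always
compare the high and low tertiles.

## Synthetic data

The single-cell generator emulates multi-patient tumor T-cell
atlases: a roster of patients x tissues x subsets; negative-binomial
UMI counts (gamma-Poisson, dispersion 0.3, log-normal cell size
factors sigma = 0.3); 11 planted MAIT markers (the signature symbols,
default log2 effect 1.5, baseline mean 3 counts/cell so the effect
survives log-CPM compression); stratum-private decoy markers the
consensus must reject; pan-T genes elevated in all T cells; and
activation/exhaustion program genes elevated in tumor-tissue cells.
MAIT cells carry TRAV1-2 with TRAJ33/12/20 drawn at 0.85/0.10/0.05
(TRAJ33 dominance is qualitative; exact proportions are generator
defaults, not claims); clone sizes are geometric (p = 0.6, mostly
singletons), clones are tissue-private or multi-tissue with
probability 0.3, and a paired-treatment mode plants post-treatment
expansions by re-weighting clone draws. Ground truth (labels, clone
memberships, marker list) is emitted alongside.

The bulk generator uses a hierarchical composition — total T fraction
~ Beta(2, 3) (immune-hot vs -cold variation) and within-T Dirichlet
shares with MAIT smallest — because the trimming rules presuppose that
MAIT markers co-vary with T infiltration, which a flat composition
does not produce. Expression is the fraction-weighted mixture of
subset profiles on the TPM scale plus Gaussian noise (sigma = 0.5) on
log2(TPM+1); MR1 is coupled to the standardized MAIT fraction.
Survival times are exponential with hazard h0 exp(beta z), z the
standardized true MAIT fraction, beta = 0.5 per SD and h0 = 1/1000
per day by default; censoring is independent exponential with its rate
solved numerically so the expected censored fraction matches the
target (30%).

What the generators do *not* emulate: gene-length effects (CPM stands
in for TPM), doublets and ambient RNA, batch structure, dropout beyond
NB sampling, patient-level expression heterogeneity, and real
marginal distributions gene-by-gene. Passing tests therefore show the
procedures are correct and well-calibrated under their stated models,
not that the biological conclusions transfer to any particular real
cohort.

## Problem sizes used in the checked analyses

Simulation-based checks run at: consensus recovery on 3 cancers x 3
tissues x 4 subsets x 200 cells (~14k cells, ~850 genes); pseudo-bulk
validation on a 15k-cell pool with 300 samples of 3,000 cells (plus a
500-sample variable-n round in the analysis driver) — that scenario
plants markers at log2 effect 3.0 rather than the 1.5 used for
signature derivation, since abundance estimation rests on the
signature genes' strong specificity to MAIT cells (SLC4A10-like
contrast), not on the minimal effect detectable by a DEG test; null error
control of the hierarchical test on 2,000 genes x 150 cells x 200
replicates; Cox recovery/coverage on n = 600 x 200 replicates and
log-rank null calibration over 1,000 simulations. These sizes give
stable Monte-Carlo estimates while keeping the full suite around a
minute or two of compute.

## Known limitations

* The moderated model is one-way only: no covariates, voom weights,
  duplicate correlation or random effects.
* Trimming can, in noisy cohorts, remove the anchor gene itself via
  rules (2)/(3); only rule (1) exempts it.
* The tertile Cox contrast discards the middle third of samples; the
  continuous mode uses all of them but answers a different question.
* MAD-based outlier removal is a single pass by design; it is not
  idempotent for heavy-tailed score distributions.
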