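# Methods

## The stoichiometric-imbalance model

The package operationalises one hypothesis: in healthy cortex the expression
of a set of disease-associated genes is kept in tight *relative* balance —
strong co-expression modules — and in affected individuals a small, varying
subset of these genes departs from the level predicted by its co-regulated
partners, even when its absolute level stays within the normal range.

For individuals i = 1..m, genes j = 1..n and resampling iterations k = 1..p,
a modelling subset M^k of the healthy controls (HC) is drawn and every gene is
regressed on the other n−1 genes plus five covariates (age, sex, ethnicity,
RIN, PMI) by LASSO. Residuals are computed only for individuals outside M^k:

    wsr[i,j,k] = R2[j,k] · (y[i,j] − ŷ[i,j,k]) / mean_l(y[l,j])

where R2[j,k] is the model's in-sample fit and the denominator is the mean
observed log2 RPKM of gene j over *all* individuals. Averaging over the
iterations with i ∉ M^k gives WSR[i,j]; standardising each gene by the HC
mean and SD gives sWSR[i,j]; and the per-individual score is

    SI[i] = (1/n) Σ_j |sWSR[i,j]|.

A gene–individual pair is called *imbalanced* when |sWSR| > 2.

Diagnosis probabilities are obtained by leave-one-cohort-out logistic
regression of diagnosis on the per-gene sWSR (and, as a comparator, on
HC-standardised covariate-residualised absolute expression), fitted on the
pooled samples of the other cohorts. Performance is summarised
threshold-free: two-sided rank-sum p, AUC (Mann-Whitney with 0.5 per tie) and
Nagelkerke pseudo-R² converted to the liability scale with the Lee et
al. (2012) transformation at an assumed population prevalence K = 0.02.

## Key estimation choices

* **Penalty selection.** 10-fold cross-validation with the one-standard-error
  rule: the largest λ whose CV error is within one SE of the minimum. The
  λ grid is glmnet-style, log-spaced from the data-derived λ_max down to
  λ_max/100 (the glmnet small-sample default ratio). Gene predictors are
  standardised on the modelling set; covariates are unpenalised.
* **Unpenalised covariates.** Implemented by the Frisch–Waugh–Lovell
  projection: the LASSO is solved on gene predictors and response
  orthogonalised against the covariate block, which is exactly the joint
  solution with a penalty-free block. Covariate coefficients are recovered by
  OLS on the LASSO remainder.
* **R²[j,k]** is the squared correlation of fitted and observed values on the
  modelling set. Test-set R² would be unstable at test sizes as small as 8.
* **Solver.** The path is solved by coordinate descent on the Gram matrix
  (scikit-learn's solver, called directly with warm starts; the public
  `lasso_path` is the fallback). Duality-gap tolerance 3e-3 and a 300-sweep
  cap; at these problem sizes (≤ ~100 samples, ~57 predictors) the residuals
  are insensitive to tighter settings, and the null calibration (below) is
  unchanged.
* **CV folds** are seeded deterministically from (plan seed, iteration, gene
  index in canonical order), so reruns are bit-identical and results are
  invariant to gene and sample order (genes are sorted internally).
* **Resampling plans.** Uniform control subsets without replacement; the draw
  is retried until every control is left out at least once, and when the
  iteration count is too small for that to happen by chance, the first
  ceil(pool/test-slots) iterations cycle a seeded permutation through the
  test slots (coverage by construction). Defaults mirror the study layout
  (model/test 94/71, 69/23, 67/8, 93/47); the default model size elsewhere is
  2/3 of the pool, shrunk if needed so coverage stays possible.
* **Degenerate inputs.** Genes that are constant, have zero overall mean
  (Eq. denominator) or zero HC variance are dropped with a warning. Perfect
  separation in the logistic fits falls back to a weak ridge (C = 1e4) with a
  logged warning. Rank-deficient covariate designs (e.g. a single-ethnicity
  cohort or fold) are handled by pseudo-inverse projection.
* **Wilcoxon tests** use the exact null for combined n ≤ 30 without ties,
  otherwise the normal approximation with tie correction; direction is the
  sign of the case−control median difference. BH correction is applied once,
  pooled across all genes and datasets. Medians of imbalance counts use the
  lower-median convention.

## The synthetic cohort generator

Real data for this analysis are access-controlled, so the package ships a
generator that emulates the features the method relies on, with ground-truth
labels of every injected perturbation.

Latent log2 expression of gene g in sample i is

    baseline_g + loading_g·F_i + Σ_c slope_cg·z_ic + eps_ig

with a standard-normal per-sample module factor F_i, standardised covariates
z, small random covariate slopes, and idiosyncratic noise eps. Genes are
organised in co-expression modules — by default one 24-gene module with
within-module correlation 0.8 and three smaller modules (10, 7, 5 genes;
|r| 0.6–0.65), the smaller ones loading negatively (anti-correlated with the
large module). These strengths make the fitted gene models reach the quality
observed in real cortical cohorts (many R² above 0.75). Counts are
gamma-Poisson around the latent expression, scaled by gene length and library
size, with purely technical dispersion 0.01 — subject-level biological
variation is carried explicitly by the latent terms, not double-counted in
the count noise.

Disease is injected per case: k ~ Poisson(λ = 3) genes receive an additive
shift of delta (default 2) times that gene's *conditional residual* SD — the
gene leaves its stoichiometric relation while the module factor is untouched.
Perturbation details, each an explicit config switch:

* **Direction** is fixed per gene (drawn once), matching the consistent
  per-gene over/under-expression seen across real cohorts; a per-pair random
  mode exists for null-direction experiments.
* **Only module members** are perturbable by default: imbalance is a property
  of a gene's relation to partners; an unconnected gene has no relation to
  break.
* **Concentration.** Gene choice is Zipf-weighted (exponent 0.9), giving a
  stable set of frequently hit driver genes; combined with the ~4.5%
  Gaussian baseline and ~40% detection power at delta = 2, the most-affected
  gene shows an observed imbalance fraction near the ~23% maximum reported in
  real cases.

Between-cohort heterogeneity, reflecting different brain regions and library
preps: module loadings are jittered per cohort (×U(0.7, 1.3)) and each module
gene decouples entirely with probability 0.15 per cohort (its variance
reverting to idiosyncratic); the case group's factor mean is shifted by a
cohort-specific N(0, 0.25) draw, emulating coherent disease-linked global
expression differences (medication, agonal state, cell composition) that
move whole modules together — confounding absolute levels within a cohort
while leaving residuals from partners unchanged.

A panel of 54 analysis genes is embedded among 300 independent background
genes that carry most of the library mass, as in real bulk RNA-seq where the
panel is a tiny transcriptome fraction. Without the background, per-sample
normalisation (library size, RPKM) would absorb the shared module factor and
destroy the co-expression the panel is built to show. Background genes are
never perturbed and are excluded from the analysis gene set.

Covariates are drawn from plausible post-mortem ranges (age 18–90, RIN 5–9,
PMI 5–50 h, binary sex and ethnicity); cohort sizes default to the study
layout (71/165, 35/93, 73/75, 125/142 cases/controls).

### What the generator does not emulate

Isoform structure, within-cohort batch effects beyond the five covariates,
non-Gaussian expression marginals, ancestry structure beyond a binary label,
and any real gene identities. Passing tests on this generator show that the
pipeline recovers the *kind* of signal the model posits under realistic
sizes and noise — not that real cohorts contain that signal.

## Validation experiments and problem sizes

* **Null calibration.** On null cohorts (delta = 0, 54 genes, 75 cases + 150
  controls, 100 iterations of a 100/50 control split) the mean per-gene
  fraction of controls with |sWSR| > 2 should equal the Gaussian tail mass
  2(1−Φ(2)) = 4.55%. The acceptance script averages 10 such replicates; the
  test suite uses 4.
* **Equation equivalence.** On a 4-gene, 20-sample, 2-iteration instance the
  pipeline output matches a loop-based recomputation of the three defining
  equations to 1e-10.
* **Leakage audit.** Every run re-derives, from the plan alone, how many test
  iterations each individual should have contributed and asserts agreement
  with the counts actually used.
* **Signal recovery.** Three replicate four-cohort studies at the study's
  sample sizes (delta = 2, λ = 3, study model sizes, 50 iterations — a
  desk-scale reduction of the study's 100–1000) must show case-control SI
  separation (median Wilcoxon p < 0.01) and the relative-over-absolute
  ordering of cross-cohort probability AUCs in ≥ 3 of 4 cohorts.
* **Negative controls.** Swapping the modelling group to cases preserves the
  per-gene direction pattern (> 80% sign concordance); splitting controls in
  two and testing one half against the other yields zero FDR-significant
  genes in ≥ 9 of 10 seeds.

## Known limitations

The relative-versus-absolute AUC ordering is a small-margin property at these
sample sizes: in a linear-Gaussian world an ideal classifier on absolute
levels implicitly residualises and can match the relative one, so the
ordering rests on the between-cohort heterogeneity described above and on
modest margins (~0.01–0.05 AUC); single replicates can invert it by chance,
which is why the validation aggregates three. The LASSO residuals carry
estimation noise from finite modelling sets that attenuates the relative
signal; iteration counts beyond ~50 reduce only the resampling component of
that noise, not the model-error component. The PCA outlier screen (6·MAD on
PC1–2) is an automated stand-in for what is, in practice, a visual decision.
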