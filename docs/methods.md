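# Methods

This note documents the statistical model behind `bactexclude`, the choices
made where the design was genuinely open, and what the synthetic-cohort
experiments do and do not demonstrate.

## The problem and the estimand

The binary outcome throughout is *any bacterial* infection (bacterial-alone,
B, plus mixed viral–bacterial, VB) versus *nonbacterial* (viral-alone, V)
acute respiratory infection, diagnosed from whole-blood gene expression.
Non-infected controls (NI) never enter model fitting; they are scored
separately to check that a signature trained on infected patients does not
call healthy blood "bacterial". The deliverable is a sparse linear risk
score on standardized log2(CPM+1) expression together with a classification
threshold anchored at 90% sensitivity, because the intended clinical use is
*ruling out* bacterial infection: a false "nonbacterial" call risks
withholding needed antibiotics, so sensitivity is the protected quantity
and specificity is whatever the score can then deliver.

## Preprocessing cascade

Order: (1) mean-CPM gene filter, (2) PCA sample-outlier removal,
(3) CPM recomputed on the retained samples, (4) batch-variance gene filter.

* **CPM and the log transform.** CPM(g, s) = count / library size × 10⁶ with
  library size = column sum. The log transform is log2(CPM + 1); the
  pseudocount of 1 is the conventional zero-safe choice and puts a zero
  count at exactly 0.
* **Mean-CPM filter.** A gene is removed iff its mean CPM across samples is
  *strictly below* the threshold (default 2); equality is retained, matching
  the usual reading of a "< 2" rule.
* **PCA outliers.** PCA on gene-centered log2(CPM+1); a sample is an outlier
  iff any of its first `n_components` (default 2) scores lies more than
  `sd_multiplier` (default 6) robust SDs (1.4826 × MAD) from the component
  median. The robust location/scale makes the rule insensitive to the
  outliers it is hunting; 6 robust SDs keeps the false-positive rate on
  clean cohorts effectively zero (verified by simulation in the test
  suite). Note that a *uniform* shift of a sample's counts is pure library
  size and is removed by CPM normalization — real outlier samples (and the
  generator's planted ones) are heterogeneous across genes.
* **Batch-variance filter.** Per gene, a one-way (batch) variance-component
  decomposition by method of moments: σ²_within = MSW and
  σ²_between = max(0, (MSB − MSW)/n₀). Genes with between-batch fraction
  σ²_b/(σ²_b + σ²_w) above 0.5 are removed — a gene whose variation is
  mostly batch is useless to a cross-batch classifier. Batches with fewer
  than two samples are excluded from the estimate with a warning; with
  fewer than two usable batches the rule is vacuous.
* CPM is recomputed after sample removal because removing samples changes
  nothing per column, but downstream statistics should be a function of the
  retained data only; it is *not* recomputed after the final gene filter,
  so reported CPM keeps the library sizes of the expressed-gene universe.

No batch-effect *correction* is applied anywhere: batch is handled by
filtering batch-dominated genes and by using batch as the cross-validation
unit, never by adjusting expression values.

## Differential expression

A deliberately compact negative-binomial Wald test used for ranking and for
the leave-one-batch-out consistency analysis — not a reimplementation of a
full DE framework (no GLM with Cox–Reid dispersion adjustment, no LFC
shrinkage, no independent filtering, no count-outlier refitting; batch is
not a covariate in the test, a gap the LOBO analysis is designed to probe).

* **Size factors**: median-of-ratios over genes nonzero in every sample,
  rescaled to geometric mean 1; total-count ratios as a warned fallback.
* **Dispersions**: per-gene method-of-moments α̂ = max(0, (s² − μ̄)/μ̄²) on
  normalized counts within each outcome group, pooled with (n−1) weights,
  then shrunk toward a fitted parametric trend α(μ) = a₀ + a₁/μ with fixed
  weight 0.25 on the log scale. Estimates at the floor (no overdispersion
  evidence) stay at the floor rather than being pulled up to the trend, so
  Poisson-like genes keep α ≈ 0. The shrinkage weight trades a small bias
  for variance reduction at these sample sizes; type-I error of the
  resulting Wald test is within 0.05 ± 0.01 under label permutation (checked
  in the acceptance suite).
* **Wald test**: log2FC = log2(μ̂₁/μ̂₀) of group means of normalized counts,
  with a delta-method standard error from Var(K/s) = μ/s + αμ²; two-sided
  normal p; Benjamini–Hochberg q. Genes with zero counts in both groups are
  reported with log2FC 0, p 1, and flagged.
* **LOBO consistency**: the core set is the full-data significant genes that
  remain significant when each batch is left out in turn; the fraction
  |core| / |full-data significant| is the stability summary (NaN when
  nothing is significant; folds that empty a class are skipped with a
  warning).

## The signature estimator

The estimator is a hard-thresholded, mostly relaxed, L1-penalized logistic
regression tuned by leave-one-batch-out resampling.

* **Lasso path.** Cyclic coordinate descent on the IRLS quadratic
  approximation, warm-started along a decreasing log-spaced penalty path
  (default 20 values down to 0.02·λ_max), intercept unpenalized, working
  probabilities clipped to [10⁻⁷, 1−10⁻⁷]. Sequential strong rules restrict
  each solve to a small candidate set; a full-gradient KKT check then admits
  any violators, so solutions are exact (KKT gaps are verified to 10⁻⁶ and
  in practice sit near machine precision; objectives match an independent
  generic convex solver to < 10⁻⁵ in the acceptance suite). Under a
  sparsity budget the path stops early once the active set outgrows
  `max(30, 5 × budget)` — the dense tail can never be selected.
* **Relaxation.** β(γ) = γ·β_lasso + (1−γ)·β_refit, the standard relaxed-
  lasso convex blend; β_refit is the unpenalized logistic refit on the
  active set (damped Newton; a quasi-separable refit falls back to a tiny
  ridge of 10⁻⁶ with a warning). "Mostly relaxed" is realized as a γ grid
  {0, 0.1, 0.25, 0.5, 1} with tie-breaking toward small γ. Refits are
  attempted only for supports up to 30 genes; beyond that the grid point is
  marked invalid (such models cannot meet the parsimony budget anyway).
* **Hard thresholding.** Blended standardized coefficients with |βⱼ| < τ
  (grid {0, 0.05, 0.1, 0.2}) are zeroed and the surviving support is refit
  at the same γ. Thresholding acts on fitted coefficients (an alternative
  formulation would threshold univariate statistics before fitting; the
  coefficient form keeps the estimator a pure post-processing of one fit).
* **Tuning and evaluation.** All tuning folds are leave-one-batch-out.
  Selection maximizes *pooled* held-out AUC (the per-fold mean is reported
  alongside) subject to a median support size within the sparsity budget
  (default 6, disable with `None`); exact ties break toward sparser models,
  then larger λ, then smaller γ, then larger τ. Performance is estimated by
  *nested* LOBO: each outer batch is scored by a model whose tuning and
  fitting saw only the other batches. The per-gene centering/scaling
  transform is fit inside each training fold — a fold's model is provably
  independent of its held-out batch (the test suite corrupts a held-out
  batch and checks the fold's coefficients are bit-identical). The final
  model is tuned by a single (non-nested) LOBO over all batches and fit
  once on all training data; its JSON serialization records that the
  coefficients live on the standardized log2(CPM+1) scale, with the
  centering/scaling constants embedded.
* Fitting is deterministic given data and grid; the only randomness in the
  package is in the generator, governed by one integer seed.

## Threshold, predictive values, validation

AUC is the Mann–Whitney probability with ties counted ½. The operating
threshold is the largest t with Se(t) ≥ target under "score ≥ t ⇒
bacterial"; since Sp is non-decreasing in t this maximizes specificity
subject to the sensitivity floor, and the search over distinct observed
positive scores is exact (verified against exhaustive cut-point search).
NPV(π) = Sp(1−π)/(Sp(1−π) + (1−Se)π) and PPV(π) = Se·π/(Se·π + (1−Sp)(1−π))
are reported on a prevalence grid {0.05, …, 0.50}, covering the plausible
range for bacterial ARI in hospitalized adults. External cohorts are scored
both through the training transform ("carried") and through constants refit
on the external cohort itself ("refit"); the dual report exposes how much
performance depends on cross-cohort normalization, and the refit mode is
invariant to global rescaling of independently processed data.

## The synthetic cohort generator

Counts are gamma-Poisson: K_gs ~ NB(μ_gs, α_g) with
log2 μ_gs = baseline_g + δ_g(class_s) + u_{batch(s), g} + log2(L_s/10⁶),
Var = μ + αμ².

Defaults (chosen once, as the study conditions the pipeline is meant for):

| parameter | default | rationale |
|---|---|---|
| class sizes | 280 V / 129 B / 95 VB / 64 NI | study cohort structure |
| batches | 7, samples assigned at random | study design |
| genes | 8,000 | ~expressed-gene universe after filtering |
| baseline log2 CPM | Normal(5, 2) | wide, realistic expression range |
| signature | 3 bacterial-up (1.8/1.6/1.5 log2), 1 viral-up (2.0) | a parsimonious strong host-response panel; the viral-up gene emulates an interferon-induced gene, elevated in V, attenuated (×0.5) in VB |
| VB mixing | bacterial effects in full + 0.5 × viral effect | mixed infections carry the bacterial response; the interferon axis separates V / VB / B |
| weak background DE | 70% of genes, effects Normal(0, 0.15) truncated at ±0.4 log2 | the host response is broad but mostly modest; truncation keeps the planted signature in the extreme tail of the effect distribution, which is precisely why such genes are selectable |
| dispersion trend | α(μ) = 0.08 + 3/μ, log-normal scatter 0.25 | typical bulk RNA-seq mean–dispersion shape |
| batch shifts | per (batch, gene) Normal(0, 0.25 log2) | mean shifts only; magnitude is a placeholder (no published estimate exists), so batch-sensitivity conclusions are qualitative |
| library sizes | log-uniform 4–20 million | typical depth spread |
| outliers | off by default; when planted, per-gene Normal(0, 3 log2) shifts | heterogeneous by necessity — a uniform shift is invisible after CPM |

The generator writes the same TSV/CSV formats the pipeline reads, plus a
ground-truth record (planted effects per class, DE status, an oracle score).
The *oracle score* is the planted-effect-weighted sum of log2(CPM+1) over the
signature genes — the linear discriminant available to an observer who knows
the generative effects — and its AUC is the reference against which the
fitted pipeline's cross-validated AUC is judged. A validation-cohort mode
redraws baselines, batches, dispersions and library sizes (optionally
rescaled) while keeping the planted biology, emulating an independently
processed external dataset.

What the generator does **not** emulate: gene–gene correlation beyond class
structure, gene length and GC effects, batch-by-class confounding,
read-level artifacts, or clinical heterogeneity within adjudicated classes.
Passing the simulation studies therefore demonstrates the *procedure* is
correct and calibrated under its assumed noise model, not that a 4-gene
panel would perform identically on real patients.

## Simulation study scales

Replicate studies run on reduced cohorts — 2,000 genes, 250 samples in the
study's 280:129:95 class ratio across 7 batches — which preserve per-gene
power characteristics while keeping many-replicate experiments cheap. For
the recovery study, planted effects are 0.9 log2 (bacterial-up) and 1.1
(viral-up), placing each signature gene's single-gene AUC around
0.83–0.90 — informative but far from separation, so that recovery is a real
test of selection rather than a foregone conclusion. In the
strong-signal LOBO-consistency study, background effects are drawn with sd
1.0 truncated at ±2.5 so that the significant set is dominated by decisively
non-null genes; the batch-corruption arm plants a class-dependent
exaggeration of 20% of DE genes inside one batch (the corrupted batch pushes
bacterial samples along, and viral samples against, each gene's effect
direction), the canonical mechanism by which one sequencing run can drive
apparent discoveries.

## Known limitations

* The NB Wald test is a two-group test; designs with covariates (age, site,
  batch-in-model) are out of scope.
* Near-separable refits (common when the signal is strong) rely on the
  ridge-stabilized fallback; coefficient *magnitudes* from such refits are
  not interpretable even though the induced ranking — and therefore AUC and
  thresholds — is stable.
* The PCA outlier rule and the batch-variance cutoff are reasonable
  conventions, not estimates of any particular study's unstated criteria;
  both are configuration options.
* With very strong planted signals the held-out AUC saturates and the
  sparsity tie-break may select a subset of the planted genes — parsimony
  and completeness of the recovered panel trade off exactly at the
  performance ceiling.
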