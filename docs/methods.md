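# Methods

## Model and procedure

The pipeline targets the association between two blocks observed on
the same `n` subjects: a panel of `q` SNPs coded 0/1/2 (wildtype,
heterozygous, homozygous-rare) and `p` repeatedly measured
quantitative risk factors with irregular visit schedules.

### Step 1 — longitudinal summarization

Each risk factor is modelled separately with a linear mixed model

    y_it = β₀ + β₁ t_it + Σ_l γ_l z_il + b0_i + b1_i t_it + ε_it,
    (b0_i, b1_i) ~ N(0, D),  ε_it ~ N(0, σ²),

fitted by REML (statsmodels MixedLM) with an unstructured 2×2 `D`.
Each subject is summarized by the empirical BLUPs `(b0_i, b1_i)` —
their deviation from the population's intercept and slope — and by
the conditional prediction standard errors (square roots of the
diagonal of the conditional covariance of `b_i` given the data). The
weight matrix `W` is the elementwise reciprocal of the squared
standard errors, so a subject's poorly-determined summaries carry
less weight downstream. Binary covariates (treatment, sex) enter as
fixed main effects; a trial-style variant adds the baseline
measurement as a fixed covariate with post-baseline times.

Assumptions: linear subject trends, Gaussian random effects and
noise, covariates acting additively on the mean. Time is centered and
scaled to unit variance before fitting: slopes are reported per
standardized time unit, and a unit-scale time axis is required in
practice — with raw-year time the slope variance can sit three
orders of magnitude below the intercept variance and the REML
optimizer reliably stalls. Response values are centered only.

A phenotype whose intercept and slope BLUPs are essentially collinear
carries no separate trend information (the paradigmatic case: a risk
factor with no real time effect, where the estimated `D` collapses to
rank 1). Its slope column is removed. The screen triggers at
`|corr(b0, b1)| ≥ 0.95`: REML estimates approach the boundary of the
covariance space without reaching it, so truly rank-1 random-effect
distributions produce BLUP correlations of ~0.98–0.9995 depending on
the optimizer path and visit structure, while regular intercept/slope
pairs in this setting stay at or below ~0.75. An exactly collinear
pair (correlation 1) is always dropped. Near-singular fitted `D`
matrices are deliberately retained (they are the degeneracy signal); a
diagonal-`D` refit is attempted only when the optimizer raises.

### Step 2 — penalized nonlinear CCA

The two blocks are related by an alternating two-block regression
(the regression formulation of canonical correlation analysis):

* **Phenotype side.** Given the SNP variate `ξ`, the weights `u` are
  fitted by cyclic univariate weighted least squares: coordinate `j`
  is regressed on the partial residual `z = ξ − Y₋ⱼu₋ⱼ` with weights
  `W[:, j]`. The sweeps only touch the data through the m×m
  cross-products `M[j,l] = (WⱼYⱼ)ᵀYₗ` and `b[j] = (WⱼYⱼ)ᵀξ`, so they
  are run in coefficient space (identical iterates, O(m²) per sweep);
  if strong collinearity (a deflated `Y`) stalls the sweeps, the
  fixed-point system `(M + ridge·diag)u = b` is solved directly. From
  the second canonical pair onward a small ridge (default 1e-3,
  scaled by the mean weight) is added to each univariate denominator;
  with equal weights and orthonormal `Y` this shrinks all coordinates
  uniformly and leaves the direction unchanged.
* **SNP side.** Every SNP is re-scaled against the current `ω` each
  iteration: the unrestricted quantification of category `k` is the
  mean of `ω` over subjects in that category; the restriction is the
  count-weighted least-squares projection onto the monotone cone,
  computed by pooled-adjacent-violators in both genotypic directions
  with the better-fitting direction kept (ascending on ties). Pooling
  automatically produces the dominant (`c0 ≠ c1 = c2`), recessive
  (`c0 = c1 ≠ c2`) and constant patterns, so the projection is the
  least-squares-optimal member of the union of the four allowed
  effect families. Transformed columns are standardized; constant
  solutions become all-zero columns. The per-SNP scores
  `s_j = x*_jᵀ ω / n` (correlations, since both sides are
  standardized) are soft-thresholded, with λ set each iteration to
  the midpoint of the k-th and (k+1)-th largest |s_j| so exactly the
  requested number of SNPs survives (ties at the boundary keep all
  tied SNPs). With selection disabled the SNP side is an exact
  least-squares regression, which makes the procedure equivalent to
  classical CCA on fixed columns — the UST update is a deliberate
  diagonal approximation used only when sparsity is requested.

Normalization fixes `ω` and `ξ` to unit variance, so the canonical
correlation is a plain Pearson correlation; signs are flipped so the
largest-|weight| SNP has a positive weight. Convergence is declared
when `u` and `v` both move by less than 1e-6 (max 200 outer
iterations). The alternating objective is multimodal; the fit is
restarted from `n_starts` (default 3) initial variates — the
standardized row mean of the additive-coded genotype matrix, then
seeded random vectors — and the restart with the largest canonical
correlation is kept. Restarts are deterministic given the seed.

Successive pairs: `Y` is residualized on `ω` (ordinary least squares
per column, guaranteeing exactly zero correlation between residual
columns and `ω`) and re-standardized. Optionally, SNPs selected in
earlier pairs keep their first fitted transformation frozen, so the
same variable cannot be re-optimized twice — recommended for small
SNP panels where supports are likely to overlap.

### Support-size selection

The estimation subjects are split into k folds (seeded, by subject).
For every candidate support size the model is fitted on the training
folds and applied — training-fold standardization, quantifications
and weights, no refitting — to the held-out fold; the criterion is
the mean over folds of |ρ_train − ρ_validation|, which grows as the
model overfits. The null reference permutes the validation SNP
variate within each fold (default 20 times per fold) while keeping
the phenotype variate fixed. A candidate size is *separated* when its
criterion lies below the 5th percentile of the pooled permuted
criterion at that size; the chosen size is the criterion minimizer
among separated sizes, optionally inflated by a safety multiplier (a
practice used when one prefers to err toward including borderline
SNPs). If no size separates, a no-signal verdict is returned instead
of a size. The held-out test set is split off before any of this and
is touched only by the final `apply`.

## Preprocessing defaults

* Friedewald LDL: `TC − HDL − 0.2·TG` (mg/dl); negative values flag
  the sample for exclusion.
* Subjects: ≥ 2 observations of every phenotype; subject-level
  genotype missingness ≤ 5%.
* SNPs: monomorphic SNPs and SNPs with ≥ 5% missing calls removed.
* Genotype classes with < 1% observed frequency merge into their
  genotypic neighbour (homozygous-rare into heterozygous), repeated
  until no class is rare; SNPs collapsing to one class are removed as
  monomorphic.
* Remaining missing calls are imputed from the SNP's marginal
  category distribution, one seeded stream consumed column by column.

Filter order: subjects, then SNP filters, then collapsing, then
imputation.

## Synthetic cohorts

The generator emulates longitudinal cohort structure: per-subject
visit counts drawn from a range, scheduled visit times with uniform
jitter, subject-specific linear trends from a bivariate normal,
binary treatment/sex covariates, independent SNPs in Hardy–Weinberg
proportions with MAF drawn uniformly per SNP, and cell-level genotype
missingness. Causal SNPs act on the *latent* intercepts or slopes
through additive (−1/0/1), dominant (−1/1/1) or recessive (−1/−1/1)
encodings scaled to an effect size in SD units of the target — so the
method's working assumption (SNPs shift levels/trends, not individual
measurements) holds exactly under the alternative; a per-visit effect
mode exists for misspecification checks. An effect `β` induces a
latent univariate correlation `β/√(1+β²)`; correlations against the
*fitted* summaries are attenuated by BLUP estimation error (factor
~0.7 under the default visit/noise regime).

Named designs: a population-cohort style (7 phenotypes, ≤ 4 jittered
visits, one degenerate glucose-like phenotype whose slope is a
deterministic multiple of its intercept, a 5-SNP causal cluster
acting on one intercept column at β = 0.45, i.e. ~0.25–0.3 observed
univariate correlation — grouped configuration of associated variants
in one gene region) and a trial style (3 phenotypes, scheduled
post-baseline visits in months, a 2-SNP causal cluster). What the
generator does **not** emulate: linkage disequilibrium between SNPs,
population stratification, non-linear trends, informative dropout,
measurement-batch effects. Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated model,
not robustness to those real-data features.

## Numerical choices

* Effect-type naming of a fitted transformation treats adjacent
  quantifications as tied when their gap is ≤ 0.1 of the
  quantification range. Exactly tied (pooled) values are always
  detected, but with a noisy target PAVA pools only when the sample
  category means happen to violate the ordering — roughly half the
  time under a true dominant/recessive effect — so a practical band
  is required for the label to be recoverable; "constant" still
  requires a range ≤ 1e-8 so that constant ⇔ all-zero column holds.
* Unobserved categories receive a vanishing weight in the monotone
  projection and inherit the score of their nearest observed
  neighbour (an unobserved middle category interpolates), so new data
  containing a category unseen in training still maps through the
  merged class.
* Backfitting tolerance 1e-8 (max 1000 sweeps); outer tolerance 1e-6
  (max 200 iterations); non-convergence is flagged, the result still
  returned.
* Degenerate inputs raise typed errors: constant columns at
  standardization, all-missing SNPs at imputation, empty supports at
  the requested penalty, infeasible support sizes.

## Problem sizes

Simulation-based checks run at n = 300–500 subjects and q = 150–500
SNPs with 20 replicates, the regime where the signal conditions
(univariate r ≈ 0.25–0.3, 5 causal SNPs among 500) are meaningful and
each replicate's seven REML fits remain the dominant cost. The
fixture generator also emits a larger cohort (n = 600, q = 2000) for
exploratory use.

## Known limitations

* statsmodels REML does not reach the boundary of the random-effects
  covariance space; degeneracy detection is therefore threshold-based
  (see above) rather than exact.
* UST ignores dependence among SNPs; correlated variables are
  selected or dropped as a group, and the induced bias makes held-out
  canonical correlations conservative — the method is a discovery
  screen, not a predictive model.
* The CV criterion compares training and validation correlations; it
  does not provide a p-value, only a separation diagnostic against
  the permutation reference.
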