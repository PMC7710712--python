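# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `parabias`.

## Effect sizes

The unit of analysis is one study × host species × parasite category, with
infected/examined counts per sex. The sex-bias effect is the log odds ratio
(male odds over female odds); its large-sample variance is the sum of the
four reciprocal cell counts. Conventions:

- **Continuity correction** (`correction=only_zero_cells`, default): 0.5 is
  added to all four cells *iff* any cell is zero — the Haldane–Anscombe
  rule, matching the default behaviour of the standard meta-analysis
  toolchain for this effect measure. `always` and `never` are provided for
  sensitivity analysis. Double-zero studies (0% prevalence in both sexes)
  are deliberately retained: under the default correction they contribute
  y = 0 with a large variance, so they stay in the evidence base while
  carrying almost no weight.
- **Species aggregation** for the comparative stage: inverse-variance
  weighted mean of the study-level log odds ratios
  (ȳ = Σwᵢyᵢ/Σwᵢ, wᵢ = 1/vᵢ, v̄ = 1/Σwᵢ). The alternative of one row per
  study with duplicated ("sister") tips is available as a pipeline switch
  (`aggregation: sister_tips`); the weighted average is the default because
  it keeps one row per species and makes the PGLS sample sizes transparent.
- **Prevalence pooling** across a species' studies (for the sex-specific
  PGLS variables): infected and examined counts are summed before dividing
  (`pooled_counts`, default); `mean_of_studies` averages per-study
  proportions instead. Count-pooling is the minimal-assumption choice and
  weights studies by their information.
- **Transforms**: natural log throughout. Prevalence and mortality are
  logit-transformed; boundary proportions (0 or 1, which can occur in
  pooled prevalences) use the 0.5-adjusted empirical logit
  ln((pn + ½)/((1−p)n + ½)). Mortality bias is log(male/female mortality),
  sexual size dimorphism is log(male/female mass), and the mating-system
  bias is the male-minus-female polygamy score (each score 0–4).

## Multilevel phylogenetic meta-analysis

Model: y = Xβ + Z_p u_p + Z_s u_s + e with u_p ~ N(0, σ²_p R),
u_s ~ N(0, σ²_s I), e_i ~ N(0, v_i) and v_i treated as known. R is the
correlation-scaled (unit-diagonal) phylogenetic matrix; effects of the same
species share one phylogenetic intercept via the mapping Z_p. X holds an
intercept plus treatment-coded moderators (sampling period, reference
*breeding*; detection method, blood parasites only, reference *microscopy*).
The pooled estimate reported per group is the intercept, i.e. the expected
sex bias at the reference levels.

- **Estimation**: REML. The objective is maximized over (σ²_p, σ²_s) ≥ 0 by
  L-BFGS-B with analytic gradients, on the raw (not log) scale so the
  frequent boundary solutions σ² = 0 are reached exactly; five
  deterministic starts (a moment-based point and four grid points scaled by
  the data variance), stopping early once two consecutive starts fail to
  improve the best objective. Convergence tolerances: gradient 1e-8,
  objective 1e-12.
- **Computation**: when every study contributes exactly one effect
  (Z_s Z_sᵀ = I), the likelihood, gradient and determinant are evaluated
  through a low-rank (Woodbury) decomposition with all factorizations at
  n_species size; otherwise a dense path builds the full marginal
  covariance. Both paths agree to machine precision and are tested against
  an independent textbook implementation.
- **Inference**: Wald Z = β̂/SE with normal-theory two-sided P and
  CI = β̂ ± 1.96·SE. Residual heterogeneity Q_E is the 1/v_i-weighted sum of
  squared residuals about the weighted-least-squares moderator fit, with
  df = k − rank(X) and a χ² upper tail; this is the quantity labelled
  "Q" in the results table.
- **Publication bias**: Egger's test, default mode `se_moderator` — the
  effect standard error appended to X inside the multilevel model, testing
  its coefficient; `precision_regression` is the classical form (regress
  yᵢ/seᵢ on 1/seᵢ, test the intercept). Asymmetry is called at two-sided
  P < 0.10. Both modes are exposed because the field's verbal descriptions
  of "Egger's test within a meta-analytic model" map onto either.
- **Influence diagnostics**: each effect is deleted in turn and the model
  fully refit (variance components re-estimated). Reported per effect: the
  shift in the pooled estimate, the studentized deleted residual
  (observed minus leave-one-out prediction, scaled by the prediction SD
  including the refit's variance components), the hat value, and a Cook's
  distance analogue. An effect is flagged when |studentized deleted
  residual| > 2 **and** hat > 2 × mean(hat); the conjunctive rule avoids
  over-exclusion, and both thresholds are configurable. Hat values are
  computed under the known sampling-variance weighting (V = diag(v), the
  same weighting as Q_E) rather than the estimated marginal covariance: a
  single extreme, ultra-precise effect inflates the REML variance
  components, which would equalize marginal-covariance leverages and mask
  exactly the points the diagnostic exists to find. The hat trace equals
  rank(X) under either weighting.
- **Pipeline structure**: per parasite class, one *overall* model over all
  of the class's effect sizes (multi-category "Combined" rows included by
  default, switchable) plus one model per single parasite category.
  Ectoparasite rows are excluded by default (a schema-supported class with
  too few species to analyze). Groups based on fewer than five studies
  carry a low-power flag. A failure in one group never aborts the others.

## PGLS with maximum-likelihood Pagel's λ

Residual covariance σ²·C(λ), where C is the covariance-scaled phylogenetic
matrix of the class consensus tree pruned to the model's complete cases and
C(λ) multiplies off-diagonal entries by λ, keeping the diagonal. For fixed
λ, β̂ is GLS with σ² profiled out; λ̂ maximizes the profile ML log-likelihood
over [0, 1] by bounded scalar search (tolerance 1e-6) with both endpoints
evaluated explicitly, so boundary optima (λ = 0 ⇒ OLS; λ = 1 ⇒ full
Brownian structure) are exact and a singular covariance at an endpoint
(e.g. effectively duplicated tips) is handled by excluding that endpoint.
t statistics use df = n − p − 1 (no adjustment for estimating λ, the
standard practice of the comparative-methods toolchain) and
σ̂² = RSS/(n − p − 1) in whitened coordinates. Adjusted R² =
1 − (RSS/(n−p−1))/(RSS₀/(n−1)) with RSS₀ from the intercept-only model
under the *same* λ̂, both in whitened coordinates. λ is estimated by ML (not
REML). Listwise deletion is applied per model and the dropped species are
logged — this is why paired single-/multi-predictor models can have
different n.

The six-model suite per parasite class: {male mortality ~ male prevalence,
female mortality ~ female prevalence, mortality bias ~ prevalence bias},
each single-predictor and with the sex's log body mass and polygamy score
(or SSD and mating bias for the sex-bias model) added.

## Trees

- **Consensus**: rooted majority-rule on clades (descendant tip sets). A
  clade is retained iff it occurs in strictly more than the threshold
  (default 0.5) fraction of trees; its branch length is the mean (default;
  median switchable) of that branch over the supporting trees, and tip
  branch lengths average over all trees. Input trees are treated as rooted
  and are never re-rooted. The candidate-tree subsample (default 1000) is
  drawn without replacement with the pipeline seed.
- **Polytomy resolution**: each polytomy is resolved by repeatedly
  splitting off a seeded-randomly chosen pair of children into a new node
  on an ε = 10⁻⁸ branch, so any root-to-tip path changes by at most
  (number of insertions)·ε.
- **Sister tips** (used by the `sister_tips` aggregation): a tip with k
  studies is replaced by k tips of the original terminal branch length at
  the original parent, then the resulting polytomy is resolved, giving the
  k tips pairwise covariance equal to the parent depth up to a few ε.
- **VCV**: C[i,j] is the depth of the MRCA of tips i and j; correlation
  scaling divides by the geometric mean of the paired diagonals. The
  meta-analysis random effect uses correlation scaling (the phylogenetic
  variance is a free parameter); PGLS uses covariance scaling (one residual
  variance against the tree's relative covariances).
- **Pruning** preserves every root-to-tip path length exactly, including
  the root-to-MRCA segment, so the VCV of a pruned tree is the
  corresponding submatrix of the full VCV.

## Synthetic-data generator

The generator emulates the data-generating process the models assume, with
defaults set to the study conditions of the blood-parasite comparative
dataset the pipeline targets: 96 host species, 1–4 studies per species
(≈2.4 effect sizes per species), per-sex sample sizes 4–500, baseline
prevalence around 20% with Brownian variation across species (variance 0.5
on the logit scale), annual mortalities around 0.4, body masses around 33 g
with Brownian log-mass variation, slight male-biased size dimorphism, and
polygamy scores concentrated at 0. The sex effect enters the male side
only, so the configured mean `delta` *is* the expected log odds ratio — the
estimand of the meta-analysis. Study-level sampling is binomial;
overdispersion is carried entirely by the study-level logit-scale deviation
(variance `sigma2_study`, default 0.1), matching the fitted model's error
structure so recovery tests are well-posed. Species-level sex-bias
deviations are Brownian with variance `sigma2_phylo` (default 0.1) against
the depth-1 correlation matrix. Mortality is optionally linked to the
latent sex-specific logit prevalence with slope `mort_slope_on_prev`
(default 0: the null), with residual phylogenetic signal `mort_lambda_true`
(default 0.9). An optional `funnel_bias` adds that multiple of each study's
expected standard error to the male logit, creating funnel asymmetry for
publication-bias power studies. Trees are Yule (birth–death optional),
grown past the final speciation by one exponential waiting time so terminal
branches are strictly positive, forced exactly ultrametric, and normalized
to depth 1. One integer seed determines every byte of the emitted files.

What the generator does **not** emulate: detection-method sensitivity
differences (the detection moderator is assigned at random, so moderator
coefficients are null by construction), taxonomic synonymy problems,
correlated sampling of the two sexes within a study, overdispersion beyond
the logit-normal study effect, and ectoparasites. Passing recovery tests
therefore shows the estimators are consistent for the assumed process, not
that real surveys satisfy those assumptions.

## Simulation study sizes used by the acceptance tests

Monte-Carlo checks run at sizes chosen to make the Monte-Carlo error small
relative to the tested bands while keeping the suite around four minutes on
one CPU:

- Wald-Z and Q calibration: homogeneous null yᵢ ~ N(0, vᵢ) with varied
  known vᵢ (k = 60, star phylogeny), 2000 replicates, fitted with the full
  multilevel REML machinery. This is the null under which the normal-theory
  Wald test is approximately exact (see Limitations).
- PGLS slope calibration: generator null link (slope 0) at 150 species,
  2000 replicates.
- Egger calibration: generator fully-null symmetric funnel at 80
  single-study species with per-sex sample sizes 10–500, 2000 replicates.
- Recovery: 200 species × 3 studies × 500 replicates at δ = 0.4,
  σ²_p = 0.2, σ²_s = 0.1; λ recovery on 200-tip Brownian data, 200
  replicates.

## Known limitations

- **Plug-in Wald inference under heterogeneity.** With variance components
  estimated and substituted as known, the pooled-effect Wald Z is mildly
  anticonservative when phylogenetic heterogeneity is present at realistic
  scales (empirically ≈0.066–0.072 rejection at α = 0.05 with 100–200
  species), because the phylogenetic variance is weakly identified from a
  single correlated tree — a well-known property of normal-theory Wald
  tests in random-effects meta-analysis. Conversely it is conservative
  (≈0.03) when the true components are zero, from the σ̂² ≥ 0 boundary.
  Small pooled-effect P values near the threshold should be read with this
  in mind; Knapp–Hartung-type adjustments are out of scope.
- **Small-sample attenuation of the log odds ratio.** The continuity
  correction shrinks extreme tables toward zero; with per-sex samples as
  small as 4, the pooled sex-bias estimate is attenuated by roughly 0.01 at
  δ = 0.4 (within the tested bias bound, but systematic).
- **λ estimation at small n** is noisy and its uncertainty is not
  propagated into the PGLS t tests (df are not adjusted); with fewer than
  ~50 species, slope tests can be mildly anticonservative when the
  predictor carries phylogenetic signal and measurement noise.
- Alternative correlation structures (Ornstein–Uhlenbeck, κ, δ),
  measurement-error (v̄-weighted) PGLS, trim-and-fill/selection models, and
  Bayesian estimation are intentionally out of scope.
- Species-name joining is exact after case/underscore normalization;
  synonym resolution is the user's responsibility and unmatched names are
  reported, never guessed.
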