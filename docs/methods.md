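# Methods

## The model

CPM treats each functional-connectivity edge (Fisher-z transformed Pearson
correlation between two regional time courses) as a candidate predictor of
a continuous behavioral score. Within each training set, edges are screened
by the two-sided test of the (partial) Pearson correlation with the score;
edges with p strictly below the selection threshold are split by
correlation sign into a positive and a negative network. A subject's
network strength is the plain sum of their selected edge values, and a
univariate linear model links normalized strength to normalized score.
Held-out subjects are normalized with the *training* mean and sd (sample
sd, ddof = 1) of both strength and score, and predictions are mapped back
to the raw score scale. The protocol therefore has exactly two globally
relevant tuning constants — the selection threshold (default 0.01) and the
network sign — and no data-dependent choices are made outside the training
fold, which is what the permutation test relies on.

Assumptions worth stating: the edge-score relation is screened marginally
(one edge at a time), the strength model is univariate and linear, and the
score is continuous and nonconstant within every training fold. Selection
uses a two-sided criterion because the sign split happens after
thresholding.

## Cross-validation and inference

- **LOOCV** re-runs selection, strength summation and the model fit for
  each left-out subject. Per-fold masks are retained; their intersection is
  the *contributing network*.
- **Repeated k-fold** (default k = 10, 100 repeats) draws seeded shuffled
  partitions (the first n mod k folds get the extra subject); the reported
  performance is the mean (partial) r of the pooled out-of-fold predictions
  across repeats.
- **Permutation test**: scores are shuffled across subjects while edges and
  confounds stay attached to their subjects; the entire CV pipeline,
  selection included, is re-run per permutation. The p-value uses the
  add-one correction (b + 1)/(m + 1) with ties counted against the observed
  statistic; the raw proportion b/m is reported alongside. The raw
  proportion can be exactly 0 for an extreme statistic, which is not a
  valid permutation p; the add-one form is the standard finite-sample
  correction. Under k-fold, each permutation runs the repeated procedure
  with a reduced repeat count (default 10, configurable up to full
  fidelity) to keep the null tractable while preserving exchangeability.
- **Confound control**: both each edge and the score are residualized on
  the confound design (with intercept) inside the training fold, with
  p-values on n − 2 − C degrees of freedom; model evaluation then uses the
  partial correlation of predictions and observations, and permutations
  recompute partial correlations with the unpermuted confounds, preserving
  the brain-confound dependence structure.

Degenerate folds (no selected edges, or constant training strength)
predict the training-mean score rather than aborting; occurrences are
counted and reported. The minimum-sample guard refuses selection when the
training n is ≤ C + 3, where the partial-correlation degrees of freedom
would drop to 1.

## Numerical choices

Inside the CV engine, training-fold correlations are obtained by
subtracting the held-out fold's contributions from globally centered
whole-sample sums (algebraically exact; verified against a brute-force
loop-and-formula implementation at small n, and against per-fold estimator
fits). Selection thresholds |r| against the exact inverse of the t test for
the fold's degrees of freedom instead of materialising per-fold p-value
arrays; p-values themselves are computed wherever they are reported.
Singleton folds without confounds take a fully vectorized leave-one-out
path; k-fold with k = n routes through the same path, making the two
schemes bit-identical. Zero-variance edges receive r = 0, p = 1 with a
warning and can never be selected. Edge vectorization is fixed as the
strict upper triangle (i < j, row-major, 0-based) and declared in every
output header. Optionally (`normalize_edges`), edges are z-scored with
training parameters before the strength sum; selection is unaffected
because Pearson correlation is invariant to affine rescaling.

## Behavioral preprocessing

Subjects with mean framewise displacement strictly above 0.3 mm are
excluded (a value exactly at the threshold is kept). Missing questionnaire
cells are imputed before composite construction — pipeline order is fixed
as filter → impute → composite — with a pluggable strategy: column means,
or the default iterative tree-ensemble imputer; observed values are never
modified and results are deterministic given the seed.

The negative-emotion composite standardizes five subscale totals (state
anxiety, depression, perceived stress, negative affect, loneliness),
eigendecomposes their correlation matrix (correlation, not covariance,
because the subscales live on different ranges), and takes the first
component. Loadings are the component's correlations with the subscales
(eigenvector × √eigenvalue), sign-oriented so their sum is positive —
eigenvectors are sign-ambiguous and the expected structure has all-positive
loadings. The composite is the loading-weighted sum of standard scores, so
it has mean zero and is invariant to affine rescaling of any raw subscale.
The eigenvalue-greater-than-one rule is reported as a warning (leading
eigenvalue ≤ 1, or a second eigenvalue > 1), not enforced.

## External generalization

The averaged model applies the arithmetic means of the LOOCV slopes,
intercepts and normalization parameters, together with the discovery
contributing-network mask, to an independent sample. Validation strengths
are normalized with the averaged discovery parameters by default, by
analogy with the averaged slope and intercept; re-z-scoring within the
validation sample is available (`normalize="validation"`) for samples on a
differently scaled questionnaire — the reported correlation is unaffected
because the re-normalization is a monotone affine map. Only the correlation
(scale-free) is the reported outcome; predicted scores stay on the
discovery questionnaire's scale. The positive-network path is implemented
but secondary: in practice the informative network for addiction-spectrum
scores has been the negative one.

## Synthetic data: what it emulates, and what it does not

The generator draws, per subject: a standardized latent score *u* loaded on
a one-factor negative-emotion panel (factor-score correlation 0.3 by
default) and on any configured confounds; a behavioral score
`score_mean + score_sd·u` on a 47-item questionnaire-like scale (defaults
101.07 ± 20.41); edges as Gaussian noise (sd 1) on the Fisher-z scale with
planted edges receiving an additional β·u (defaults: 12 negative edges,
β = −0.35, so the planted edge-score correlation converges to
β/√(β² + 1) ≈ −0.33); age 19.94 ± 7.13 years; sex at the 28% male fraction;
lognormal mean FD with σ_log = 0.35 calibrated so a configurable fraction
(default ≈ 1.7%) exceeds 0.3 mm; and a five-subscale panel from the
one-factor model with the reference loadings (0.78, 0.636, 0.786, 0.818,
0.756) and realistic subscale means/sds, with optional missingness. The
default test dimensions (n = 300, 60 nodes) keep simulations fast; a
677-subject / 268-node preset emulates the full parcellation scale, and
the packaged ten-region atlas reproduces the reference region sizes
(46, 21, 7, 27, 39, 25, 36, 41, 17, 9 nodes). Atlas coordinates,
hemispheres and functional-network labels are synthetic placeholders.

What the generator does *not* emulate: spatial autocorrelation among edges,
non-Gaussian tails of real z-edges and their positive mean, head-motion
artifacts that couple FD to edges unless explicitly configured, and
site/scanner effects. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated under the assumed generative model,
not that any particular effect size is attainable in real fMRI samples.
Time-series generation (for exercising the connectivity stage) draws from
a zero-mean Gaussian with a target positive-definite correlation matrix.

## Acceptance checks and problem sizes

The acceptance suite runs: exact equivalence with a brute-force oracle on
20 random instances (n ≤ 12, E ≤ 20); null calibration over 200 replicates
(n = 100, 30 nodes, 199 permutations) with the α = 0.05 rejection rate
required inside the exact binomial 95% interval [0.024, 0.087]; power and
planted-edge recovery over 50 replicates of the default signal conditions
(99 permutations per replicate, which resolves the p < 0.05 criterion with
a minimum attainable p of 0.01); the noiseless limit (β = −1, zero noise,
r > 0.99 for LOOCV and external prediction); the structural identities
(edge-count formula, mask disjointness, contributing-mask containment,
node-strength handshake Σ strengths = 2·Σ|weights|, k = n ≡ LOOCV); the
atlas grouping; and composite loading recovery at n = 500.
`scripts/acceptance.py` recomputes the same families of quantities at
slightly reduced replicate counts (100 null replicates, 20 power
replicates, 20 k-fold repeats) chosen as a sensible default runtime for a
single-CPU rerun.

## Known limitations

- Selection is marginal; correlated edges enter the strength sum with full
  weight each, and no multivariate or regularized variant (ridge/SVR CPM)
  is provided.
- Robust or rank-based edge screening is not implemented.
- The k-fold contributing network is only defined for a single repeat;
  repeated k-fold reports per-repeat performance instead.
- Scores from differently scaled questionnaires are not harmonized; only
  correlations are comparable across samples.
- The imputation contract fixes determinism and non-modification of
  observed cells, not a particular tree-ensemble hyperparameterization.
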