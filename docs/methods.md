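# Methods

## Model and geometry

A dwell-time record over `D` AOIs is treated as a composition: an
equivalence class of strictly positive vectors under positive rescaling.
All analysis happens in log-ratio coordinates. The clr transform divides
each part by the row geometric mean before taking logs; it is a linear
isometry onto the zero-sum hyperplane of R^D, which makes the Aitchison
distance an ordinary Euclidean distance and lets SVD-based PCA and distance
clustering operate directly on clr rows. Where a full-rank covariance is
needed (MANOVA, LDA/QDA), the pivot ilr coordinates are used instead: an
orthonormal basis of that hyperplane, so results are identical for any
other orthonormal log-ratio basis — a property the test suite asserts for
the Pillai statistic, classifier assignments and CV accuracy.

The group-comparison model is `x_i^k = mu_k ⊕ e_i^k` with perturbation `⊕`
(component-wise multiplication plus closure) and logistic-normal errors:
ilr(e) ~ N(0, Σ), homoscedastic across groups. MANOVA on ilr coordinates is
then classical MANOVA; LDA/QDA on ilr coordinates is classical Gaussian
discriminant analysis.

## Key formulas and conventions

- Compositional mean: closed vector of column geometric means.
- Variation matrix: `t_jk = S²(ln(x_j/x_k))`; total variance
  `totvar = (1/2D) Σ_jk t_jk`, identically the sum of clr column variances
  and of `λ_k²/(n−1)` over the clr-PCA spectrum (both identities tested at
  1e-9).
- Variance divisor: unbiased `n−1` everywhere, with a `ddof=0` switch;
  totals published by software using divisor `n` differ by `(n−1)/n`.
- Logarithms: natural. Closure: κ=1 internally, κ=100 for displayed tables.
- Pillai F approximation: `s = min(p, q)`, `m = (|p−q|−1)/2`,
  `n* = (N−K−p−1)/2`, `F = (V/s)/(1−V/s) · (2n*+s+1)/(2m+s+1)` on
  df `(s(2m+s+1), s(2n*+s+1))`; partial η² = V/s. For a 7-group design with
  1008 observations this gives df (36, 6006) on six ilr responses and
  (42, 6000) on seven raw responses.
- Mean-contrast diagnostic: `ln(g_task / g_all)` per AOI with both
  geometric-mean compositions closed to unit sum first, so the contrast is
  independent of the input closure; contrasts then sum (per task) to a
  small task-specific constant rather than drifting with raw totals.
- Covariance divisors in classification: pooled `N−K` (LDA), per-class
  `n_k−1` (QDA) — the conventional unbiased choices. Priors default to
  empirical class shares (uniform available).
- Balanced task effects: `effect(t) = mean_i(v_it − mean_t' v_it')` on a
  complete participant × task design. This two-way centring equals the
  fixed-effect estimates of a random-intercept mixed model on balanced
  complete data; unbalanced designs are rejected with a pointer to general
  mixed-model tooling. clr-scale effects are also reported as `exp(effect)`
  multiplicative changes in relative dominance.
- PCA explained-variance shares are computed from `λ_k²` (the variance
  scale, consistent with the totvar identity); the singular-value shares
  `λ_k/Σλ_j` that some software prints are exposed alongside as
  `explained_singular`.
- SVD sign convention: each loading is flipped so its largest-magnitude
  entry is positive. Agglomeration uses SciPy complete linkage, whose
  deterministic tie-handling fixes the merge order; heights are verified
  against a brute-force O(n³) oracle on small instances.
- AOI (variable) clustering uses `t_jk` itself as the dissimilarity; a
  `sqrt` flag clusters on `√t_jk` instead (same merge order under complete
  linkage, metric-valued heights).

## Zeros

An AOI never fixated by a participant yields a structural zero, which no
log-ratio admits. The default policy replaces each zero by 0.65 × the
column's minimum positive value (a simple multiplicative-style imputation)
and logs every replacement; columns that are zero everywhere are rejected
with guidance to merge or drop the AOI, and AOI aggregation (summing
durations within groups, which conserves row totals exactly) is the
preferred structural fix. Rows with zero total dwell time carry no relative
information and are dropped with a warning.

## Synthetic experiments

The generator emulates a task-instruction viewing experiment: for
participant `i` and task `k` it draws
`composition = mu_k ⊕ p_i ⊕ e_ik`, with the participant effect `p_i` and
noise `e_ik` inverse-ilr images of isotropic Gaussian draws (sd
`sigma_participant = 0.3` and `sigma_noise = 0.5` in ilr space), then
scales the row to a lognormal(ln 15000, 0.5) ms total. Defaults describe a
144-participant, 7-task, 7-AOI design whose pooled mean composition is
(12.52, 2.33, 19.21, 16.19, 20.22, 17.71, 11.82) percent over (Background,
Furniture, Kids, Maid, Man, Mother, Wife). The bundled "yarbus-like"
scenario is qualitative and illustrative only — Furniture suppressed in
tasks 3/5/7, Man elevated in task 7 — not a fit to any recorded dataset.
With the default scales each task's total compositional variance is about
`(D−1)(σ_p² + σ_e²) ≈ 2`, i.e. a tighter dispersion than large free-viewing
samples typically show; recovery tolerances in the tests are set for these
defaults.

What the generator does **not** emulate: within-session learning or order
effects, heavy-tailed or participant-specific noise scales, correlated
AOI-specific error structure, or realistic structural-zero mechanisms
(zeros are injected completely at random, never blanking a whole row).
Passing tests therefore certify the statistical machinery under its own
assumptions, not the behaviour of any particular recorded dataset.

## Calibration checks

The acceptance test suite verifies, at fixed seeds, that the stack is
calibrated under the generator's null: the ilr-MANOVA type-I error over
2000 i.i.d. logistic-normal null replicates (K=3, D=4, 25 rows per group,
sizes chosen so the whole run takes well under a minute) lies in
0.05 ± 0.02 with KS-uniform p-values; 10-fold-CV LDA accuracy is 1/7 ± 0.03
on a 1400-row null and ≥ 0.99 under strong separation; mean compositions
are recovered within 2 points (percent scale) at n = 1000 and injected clr
task effects within 0.12 at 200 participants. The participant random effect
is switched off in the type-I harness because MANOVA's i.i.d. assumption is
part of the null being calibrated; with it on, rows are positively
correlated within participants and the test is conservative by design.

## Numerical choices and degenerate inputs

Exact identities (clr zero-sum, ilr round-trips) are enforced at 1e-10 /
1e-9. clr-inverse rejects rows off the zero-sum hyperplane at 1e-8 (loose
enough for accumulated float error on long rows). `variation_matrix` clips
tiny negative variances arising from the covariance expansion to zero. PCA
rejects rank-zero input (all rows equal); MANOVA and the classifiers reject
group sizes not exceeding the response dimension and singular covariances,
naming the offending group. Stratified CV folds are drawn per class from a
seeded generator, making reports bit-reproducible; folds stratify by task
over observations, so a participant's rows may straddle train and test —
accuracy estimates are for observation-level generalisation, not
new-participant generalisation.

## Known limitations

No robust (MCD-based) estimation, no Bayesian or multiplicative-lognormal
zero imputation, no REML/unbalanced mixed models, no participant-grouped
CV. The classical track intentionally mirrors textbook practice (Pearson
correlations and PCA on raw ms) for contrast with the compositional track,
not as a recommendation.
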