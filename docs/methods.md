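# Methods

## The decomposition model

Site differences in multisite resting-state functional-connectivity data mix
two things: **measurement bias** (engineering — scanner vendor, coil,
phase-encoding direction shift every value acquired at a site) and
**sampling bias** (biology — each site recruits a different slice of the
population). The two are confounded in an ordinary multisite sample because
different people are scanned on different scanners. A traveling-subject
dataset — the same healthy participants scanned at every site — breaks the
confound: its site differences are measurement bias only.

`fcharm` fits, per connectivity edge (Fisher-z Pearson correlation between
two atlas regions), a single linear model jointly to both datasets:

```
y = x_m' m + x_shc' s_hc + x_smdd' s_mdd + x_sscz' s_scz
    + x_d' d + x_p' p + const + e,      e ~ N(0, gamma^-1)
```

with 1-of-K indicator vectors. A multisite patient row activates its site's
measurement bias, its (site, class) sampling bias, and its disorder factor;
a traveling session activates its site's measurement bias and its
participant factor. Blocks are identifiable only relative to each other, so
hard sum-to-zero constraints are imposed: `m`, each sampling-bias class and
`p` average to zero across their levels, and the healthy-control disorder
factor is the baseline (`d(HC) = 0`). A patient class observed at a single
site (autism in the default design) gets no sampling block; its site
deviation is absorbed into the disorder factor and interpreted accordingly.

### Estimation

Each edge is an equality-constrained ridge problem: minimize
`||y - Xw||^2 + lambda ||w_pen||^2` subject to `Cw = 0`. Constraints are
enforced exactly by null-space elimination — substitute `w = Zu` with `Z` an
orthonormal basis of `null(C)` and solve the reduced normal equations — not
by soft penalties. One Cholesky factorization is shared by all edges (same
design, many right-hand sides), and batch results are identical to per-edge
fits by construction. The unit tests verify the solver against an
independently assembled bordered KKT system.

Choices worth knowing:

* **Intercept is not penalized** (configurable). It estimates the grand-mean
  connectivity and should not shrink toward zero.
* **Residual variance is RSS/n.** Effective degrees of freedom are
  ill-defined under constraints plus ridge; the plain estimator is used and
  documented.
* **`lambda = 0` is refused when the constrained design is singular** (a
  multisite dataset without traveling coverage leaves site and HC-sampling
  indicators collinear) with an error that says to use `lambda > 0`.
* **Ridge weight selection** (`select_lambda`): with finite data the fitted
  measurement and sampling biases at the same site are spuriously
  (anti-)correlated even though the generating quantities are independent.
  The selector refits over a grid (default 0–20, step 1) and minimizes the
  absolute mean of the matched-site correlation families (m vs s_hc,
  s_hc vs s_mdd, s_hc vs s_scz); an optional site-permutation mode produces
  the null criterion curve. The benchmark and examples use `lambda = 1`,
  which sits on the flat part of the criterion for the default generator.

## Factor summaries

* **Magnitude moments**: per level (site/participant), the mean, population
  SD and signed cube root of the third central moment of the edge-wise
  vector; the factor-level summary is the mean across levels. Population
  (not sample) SD is used — over tens of thousands of edges the difference
  is negligible.
* **Contribution sizes**: per (subject, edge) cell the squared values of the
  six model terms and the residual are normalized by their sum; a factor's
  contribution is the average share divided by its level count. The shares
  are a partition of unity, which the tests assert exactly.
* **Dispersion tests**: Ansari–Bradley (scipy) between all level pairs of
  two factors, Bonferroni-corrected by the number of pairs (the only
  multiplicity correction implemented). The default grid (9 participants ×
  12 sites) has 108 pairs.
* **ROI projection**: per-edge effect is the median absolute value across
  levels (absolute value for a single disorder vector); an ROI's score is
  the mean over its incident edges, optionally z-scored within the factor.
* **Clustering**: measurement-bias vectors, correlation distance `1 - r`,
  average linkage with optimal leaf ordering. The linkage criterion is a
  configuration choice; published uses of this analysis rely on toolbox
  defaults and only the qualitative grouping matters.

## Sampling-bias population models

The across-edge variance `V_k` of a site's fitted HC sampling bias is
modelled against its sample size `N_k`:

* single population: `E[V_k] = xi^2 / N_k` (log form `y = -x + 2 log10 xi`),
* different subpopulations: `E[V_k] = xi^2 / N_k + sigma^2`.

The least-squares loss is on the log10 scale by default (the scale on which
both laws are written and plotted); the raw-variance scale is selectable.
Positivity of `(xi, sigma)` is enforced by optimizing their logs
(quasi-Newton), with a safeguard that the nested single-population solution
is never beaten by a worse local optimum. Model comparison uses the
small-sample criteria on variance-scale residuals `phi_k = v_k - v_hat_k`:

```
AICc = sum ln phi_k^2 + 2q + 2q(q+1)/(K - q - 1)
BIC  = sum ln phi_k^2 + q ln K
```

(`q` = 1 or 2; `K` generalizes the six-site design), plus leave-one-site-out
prediction compared by a one-tailed Wilcoxon signed-rank test with the fixed
direction "the subpopulation model has smaller absolute error". A zero
residual makes the criteria `-inf` and is flagged as a degenerate perfect
fit.

## Harmonization

* **Traveling-subject**: subtract the jointly estimated measurement bias
  `m_hat` from every row of the target data. Refuses to run when the
  traveling sessions do not cover every multisite site. Subtraction is
  linear and not idempotent (applying twice shifts twice). With a nonzero
  ridge weight the penalty couples blocks at order `lambda * m / n`, so the
  exact invariance of sampling-bias estimates under harmonization holds in
  the `lambda -> 0` limit; at `lambda = 1` the coupling is ~1e-3 of the
  bias scale.
* **GLM**: per-site mean removal. With sum-to-zero site coding the solution
  is closed-form (intercept = unweighted mean of site means; site term =
  site mean − intercept) and post-apply site means are exactly equal —
  including any disorder signal confounded with site, which is the method's
  documented failure mode.
* **Adjusted GLM**: OLS with site (sum-to-zero) plus diagnosis (HC baseline)
  indicators; only site terms are subtracted. Perfect site–diagnosis
  confounding triggers a minimum-norm fit with a prominent warning.
* **ComBat**: parametric empirical-Bayes location-and-scale model.
  Standardize each edge by the OLS fit (site indicators + diagnosis
  covariates) and pooled variance; estimate per-site additive and
  multiplicative effects; shrink with a normal prior (additive) and
  inverse-gamma prior (multiplicative), hyperparameters moment-matched
  across edges; iterate conditional posterior means (tolerance 1e-4, max
  100 iterations). Degenerate hyperpriors (single edge, identical per-edge
  scales) fall back to the unshrunk estimates. Apply restores the
  covariate scale: `(y - const - cov - s_k)/delta_k + const + cov`. The
  scale factor is per site × edge.

## Two-fold cross-validated benchmark

Multisite rows are halved within each site; traveling rows within each
(site, participant) cell (odd counts round to fold 1; the split is
deterministic under the seed, and the halves share no sessions). Per fold
direction: the traveling-subject method fits on the estimating multisite
half plus its traveling half and is applied to the whole testing dataset;
the GLM-family methods fit on the estimating multisite half alone and are
applied to the testing multisite half (traveling-only sites have no fitted
term there). The decomposition is then refitted on the harmonized testing
data. The measurement-bias summary is the mean across sites of per-site
SDs; the signal-to-noise ratios are measurement-bias SD over
participant-factor SD and over the mean disorder-factor SD. Reductions and
SNR improvements are `100 (raw - method)/raw` on the SD and on the ratios,
averaged over folds.

## Synthetic data generator

The generator draws from exactly the model above. Defaults mirror the
motivating study design: six unified-protocol multisite sites with
realistic class counts (335 HC / 81 MDD / 48 SCZ / 49 ASD = 513 rows, ASD
at one site), nine traveling participants over twelve sites on the
411-session schedule (3 sessions at nine sites, 2 at two, five 3-session
cycles at one home site, one participant a cycle short). Effect scales are
set to the magnitudes observed for each factor class in multisite
connectivity work — participant 0.0662, measurement 0.0411, disorder
0.030–0.038, between-subpopulation sampling 0.021–0.027 (Fisher-z) — so
simulations occupy the same regime; they are scale-setting presets, not
test targets. Centered blocks are inflated by `1/sqrt(1 - 1/K)` before
re-centering so the configured SD is the SD of the centred (estimable)
vectors, and re-centering matches the estimator's constraints, making
recovery unbiased rather than alias-shifted.

Values the study design does not pin down are explicit synthetic choices:
the scan-to-scan noise SD (0.03 — real studies do not publish their noise
precision), the within-population subject SD (set equal to the
participant-factor scale 0.0662, i.e. individual differences act as noise
in the multisite model), and the grand-mean distribution
(N(0.15, 0.30^2), a realistic Fisher-z connectivity spread). Under the
different-subpopulation mode, class site-means are `beta_k ~ N(0, sigma^2)`
and subjects scatter `N(beta_k, xi^2)`; the single-population mode is
`sigma = 0`.

What the generator does **not** emulate: spatial correlation among edges
(the model treats edges independently, so none is generated), non-Gaussian
tails, scanner drift within a session, motion artifacts at the connectivity
level, or age/sex structure. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-data violations of them. The per-edge site ANOVA
flags nearly all edges on default synthetic data — biases are present on
every edge by construction — whereas real data show site effects on a
minority of edges.

When a requested edge count is not a triangular number the generator uses
the first `n_edges` slots of the smallest enclosing atlas, which is fine
for every analysis here but means `devectorize` round-trips only for full
triangular edge counts.

## Problem sizes

The test suite and the acceptance script run the full design (924 rows) at
250–2,000 edges, Monte-Carlo checks at 200 replicates, and the CV benchmark
at 300–500 edges — sizes at which every statistical property tested is
comfortably resolved while a complete run takes seconds. The estimator's
cost is one 37-column factorization plus a solve per edge, so scaling to
the full 35,778 edges is linear and unproblematic.

## Known limitations

* Sampling-bias recovery at small sites is noise-limited (a 10-subject
  site's estimate carries subject scatter `xi/sqrt(10)` on the bias scale);
  this is a property of the design, not the solver.
* No hierarchical pooling across edges inside the decomposition (each edge
  is fitted independently); empirical-Bayes coupling across edges is future
  work.
* Nonparametric ComBat priors, covariate-continuous ComBat and longitudinal
  extensions are out of scope.
* The preprocessing module starts from extracted ROI time series; voxel-
  level spatial preprocessing and field-map distortion correction are out
  of scope. The scrub-then-filter order and the backward-difference
  derivative scheme are documented defaults where conventions differ, and
  the motion-exclusion rule (removed-volume count above mean + 3 SD, or
  retained count below mean − 3 SD) is selectable because published
  phrasings of this rule are ambiguous.
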