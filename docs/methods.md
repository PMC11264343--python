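# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Consecutive disparity index

For a seed-crop series p_1..p_n (n ≥ 2, p_i ≥ 0, no gaps) the masting
intensity is D = (1/(n−1)) Σ |ln((p_{i+1}+k)/(p_i+k))| with pseudo-count
k = 1 by default (exposed as a parameter; k = 0 is allowed only for
strictly positive series, where D becomes exactly scale invariant). A
constant series yields D = 0 with a `zero-variance` flag rather than an
error — the formula is well defined there. Missing years inside a series
are a hard error: no imputation rule exists for masting records, and
inventing one would silently change D. Series shorter than a configurable
minimum length (default 2, the formula's own minimum; no stricter published
rule exists) are excluded with a logged reason, the monocarpic
single-fruiting case being the motivating exclusion.

Traits are log10-transformed before analysis (the index itself uses natural
log, as in its definition). Useful closed form: for i.i.d. normal log
increments with SD σΔ and crops large enough that the pseudo-count is
negligible, E[D] = σΔ·√(2/π); for a stationary AR(1) log series with
innovation SD s and coefficient φ, E[D] = 2s/√(π(1+φ)). Both are used as
test oracles.

## Trees and covariance

Newick trees are read with dendropy; duplicate tips and missing branch
lengths are hard errors, polytomies are accepted and flagged. Tip labels
are canonicalised (trim, collapse whitespace, underscores ≡ spaces); no
fuzzy taxonomic matching. Ultrametricity is checked to a relative 1e−6 and
non-ultrametric trees are accepted with a warning, since mega-tree
pipelines can emit slightly non-ultrametric branch lengths.

The Brownian covariance has C_ij = shared root-to-MRCA path length and is
normalised to height 1 by default for model fitting, so the phylogenetic
and residual variances are on one scale and comparable across trees.
Pagel-style rescaling multiplies off-diagonal entries by λ ∈ [0, 1].
Pruning uses the induced subtree with degree-2 nodes suppressed and their
edge lengths summed, so tip-to-tip path lengths are preserved exactly.

Polytomies are resolved deterministically (seeded, zero-length edges)
wherever a bifurcating tree is required: independent contrasts and the
sister-difference traversal. For covariance they are retained as-is.

## Pagel's λ

The likelihood is multivariate normal with mean μ·1 and covariance
σ²·(λC_off + diag C). μ (GLS mean) and σ² (ML variance) are profiled in
closed form; λ is maximised on [0, 1] by bounded scalar search (tolerance
1e−8), with both endpoints evaluated explicitly so boundary optima are
exact. The upper bound is 1.0 — not the algebraic λ_max of the tree —
matching the estimator's conventional range. On ultrametric trees
(constant diagonal) every likelihood evaluation runs through one symmetric
eigendecomposition of C in O(n), which is what makes permutation tests and
200-replicate calibrations cheap; the general path factorises V(λ) by
Cholesky. A star tree makes λ unidentifiable (flat likelihood); the fit is
returned flagged `unidentifiable` with λ̂ = 0 instead of an arbitrary
interior value.

Two significance tests are provided and both reported: a likelihood-ratio
test of λ̂ against λ = 0 with the boundary-corrected ½χ²₀ + ½χ²₁ null, and
a tip-shuffle randomization test p = (1 + #{λ̂_perm ≥ λ̂_obs})/(n_perm + 1).
The pipeline reports the randomization p as primary, with the LRT
alongside; neither is discarded because practice varies between them.

## Fritz–Purvis D

The observed statistic d_obs assigns each internal node the unweighted mean
of its children's values (branch lengths deliberately ignored in the
traversal, per the original construction) and sums |child − node| over all
internal nodes. Two nulls, n_sim = 1000 by default and always seeded:

- random: tip-label shuffles preserving prevalence (an exhaustive
  enumeration over all prevalence-preserving assignments is available for
  small trees and is used as a test oracle);
- Brownian: continuous Brownian simulations on the tree, thresholded by
  rank (top m tips set to 1, m = observed count of ones), which preserves
  prevalence exactly.

D = (d_obs − mean d_B)/(mean d_R − mean d_B); Pr and Pb are upper/lower
tail probabilities with a +1 pseudo-count, so a reported "Pr = 0"
corresponds here to Pr < 1/(n_sim+1). If the two null means coincide the
scale is undefined and an error is raised.

## Gaussian PGLMM

y = Xβ + u + e, u ~ N(0, σ²_p·C), e ~ N(0, σ²_e·I), fitted by **ML, not
REML**: log-likelihood differences across fixed-effect structures must be
valid for AIC and the likelihood partial R², and REML's would not be.
Parameterised by the ratio h = σ²_p/(σ²_p+σ²_e): V(h) = h·C + (1−h)·I,
β profiled by GLS, the total variance by its ML estimate, and the
one-dimensional profiled likelihood in h optimised on [0, 1−1e−6] (again
O(n) per evaluation after one eigendecomposition). SEs come from the GLS
information matrix with the ML variance; coefficient tests are Wald z with
normal tails. AIC = −2lnL + 2k counting the β's and both variance
components. With the phylogeny excluded the model collapses exactly to OLS
with the ML variance, which the tests assert.

Binary predictors are coded 0/1 with the alphabetically first level as 0;
the coding is stored on every fit and echoed in reports because coefficient
signs depend on it. Rank-deficient designs fail with the collinear columns
named. Complete cases only; dropped species are warned about and the
covariance is re-restricted to the retained set.

## Phylogenetic correlation and t-tests

The evolutionary correlation of two traits is the through-origin
correlation of their independent contrasts, R = Σc_xc_y/√(Σc_x²Σc_y²),
tested with t on (n_contrasts − 1) df. A GLS alternative (correlation of
GLS-centred tip values under the Brownian covariance, t on n − 2 df) is
available behind a flag; contrasts are the default since the underlying
procedure was not further specified. On a star tree the contrasts are an
orthogonal rotation of the centred data, so R reduces to the Pearson
correlation — asserted to 1e−10 in the tests.

Group comparisons default to Welch's unequal-variance t-test on
log10-transformed values (the transformation applied to all traits);
pooled-variance and raw-scale variants sit behind flags since the exact
convention of such reported tests is often unstated.

## Likelihood partial R²

R²_lik = 1 − exp(−2ΔlnL/n) with n the number of species in the fitted
model (complete cases) — the likelihood-based coefficient-of-determination
definition. For intercept-only OLS reductions this equals the classical R²
exactly (ML variance estimates make the identity algebraic), which is a
test oracle at 1e−10. Negative values are reported as computed, never
truncated. Fixed-effect removals use a χ² LRT with df = parameter
difference; removing the phylogenetic random intercept is a boundary
comparison across covariance structures and uses the ½χ²₀ + ½χ²₁ mixture,
labelled approximate in the output. Although the source analysis phrases
this partition in terms of a "logistic regression model", the fitted model
here is Gaussian throughout, and the partition is implemented for the
Gaussian PGLMM; the phrasing discrepancy is surfaced here rather than
resolved by guesswork. The ML nesting property (a nested reduction cannot
beat the full model) is checked on every run and a violation warns loudly,
since it can only mean an optimiser failure.

## Synthetic-data generator

The generator's defaults are the study conditions: 158 species on a Yule
tree rescaled to height 1; log10 adult height with λ = 0.9 and unit rate
(strong but imperfect signal, as observed for height); binary traits from
Brownian thresholding at the study prevalences (life form 0.5, insect
pollination 78/158, gymnosperms 35/158); response fixed effects at the
published multivariate magnitudes (intercept −0.273, height 0.288, life
form −0.010, Spermatophyte −0.225, pollination 0.654, on the log10
response scale) with σ²_p = σ²_e = 0.5; and 20-year seed-crop series with
φ = 0.2 and innovation SD 1.0 around a log-crop mean of 5 — values chosen
once as realistic masting records (two decades of monitoring, mild
positive lag-1 dependence, order-of-magnitude interannual swings).

The tree simulator extends all pendant edges by the waiting time to the
next (unrealised) speciation, since stopping exactly at the n-th birth
leaves a zero-length cherry that would break contrasts. The response is
simulated directly on the log10 scale (the analysis models transformed
variables), avoiding an invented back-transformation. Optionally
(`link_series=True`) the response is realised through the seed-crop
generator instead: per-species innovation SDs are set so the expected D
matches each species' linear-predictor target, and the realised D values
become the response — this couples the disparity stage to the model stages
but changes the response's noise distribution, so both paths carry ground
truth. All generators are bit-reproducible under a fixed seed; stage seeds
are spawned from one SeedSequence.

What the generator does **not** emulate: trait-database heterogeneity and
measurement error in height, climate drivers or spatial synchrony of
masting, unequal sampling effort across species, and non-Yule tree shape.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to those real-data features.

## Problem sizes and tolerances

Monte-Carlo checks run at the sizes stated with them: Fritz–Purvis
calibration uses 200 replicates per regime on 100-tip trees with 500 nulls
(mean D within ±0.15 of its anchor); λ recovery uses 200 replicates on
200-tip trees (mean within 0.07 of 1 under Brownian simulation); effect
recovery uses 200 datasets of 300 species (mean β̂ within ±0.03 of 0.3);
permutation-p calibrations use 200 null datasets with binomial 99% bounds
at α = 0.05. The prune/covariance commutation property is verified
exhaustively over all tip subsets of size 2–5 of an 8-tip tree. Matrix
solves use Cholesky/eigendecompositions with a relative PSD tolerance of
1e−8 and a 1e−10·trace jitter fallback for simulation Choleskys.

## Known limitations

- Exact reproduction of the original 158-species results requires the
  deposited trait data and the pruned mega-tree phylogeny as inputs; the
  pipeline accepts them (CSV + Newick) but does not fetch or construct
  them, and database compilation/taxonomic standardisation are out of
  scope.
- The PGLMM supports one phylogenetic random intercept and a Gaussian
  response only; no measurement-error or multi-random-effect models.
- The Fritz–Purvis Brownian null simulates on the resolved tree with its
  stored branch lengths; alternative null calibrations (e.g. simulating on
  the unresolved tree) are not offered.
- λ estimation assumes a strictly positive-definite rescaled covariance;
  trees with duplicated tips at zero distance are rejected rather than
  regularised.
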