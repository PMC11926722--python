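# Methods

## Observation model

Weekly negative-document counts per region follow a Poisson
generalized additive model with a multiplicative decomposition of the
mean: `μ(i,t) = θ_tot · TTW(i,t) · relrisk(i,t)`. The exposure
`TTW(i,t)` and the global negative share `θ_tot` enter as a fixed
offset `log(θ_tot · TTW)` with unit coefficient; all modelling happens
in `log relrisk`, which is additive in

* a global intercept `b0` (vague Gaussian prior, precision 1e-6);
* a spatiotemporal field with a separable GMRF prior;
* one random-effect vector per categorized covariate;
* optionally a temperature × precipitation interaction.

Cells with `TTW = 0` contribute no likelihood term (the Poisson mean
would be degenerate) but keep their field coordinates, so the GMRF
smooths across them.

## Latent structure and priors

**Field.** Default `icar_ar1`: intrinsic CAR (Besag) `τ_f (D − A)` on
the region graph, Kronecker-multiplied with a stationary AR(1)
precision over weeks. The ICAR factor is the literal unscaled Besag
form (no generalized-variance scaling); the three other combinations
of intrinsic/independent space with AR/independent time are available
through `field_structure`. With intrinsic space and full-rank time the
null space of the product is "constant over regions within a week",
i.e. exactly one sum-to-zero constraint per week. These constraints
are imposed exactly.

**AR(1) parameterization.** `ar1_precision(n, rho, tau)` uses the
innovation precision `τ`: tridiagonal with diagonal
`τ·(1, 1+ρ², …, 1+ρ², 1)` and off-diagonal `−τρ`, so the stationary
marginal variance is `1/(τ(1−ρ²))`. This matches the closed forms the
tests verify against.

**Covariate effects.** Temperature has four ordered levels (cuts 15,
19, 23 °C; the first level is unbounded below so the observed minimum
of −1 °C is categorizable — the printed band "0–15 °C" cannot
accommodate it, so the first band is treated as open), precipitation
three (cuts 0.01, 0.035 in the covariate's native unit). Intervals are
left-closed/right-open with the last level closed above at +∞, so
boundary values like 0.035 fall in the *higher* category ("0.035 and
higher"). Effects carry chain priors: independent `τ·I` by default, or
an AR(1) chain over adjacent levels. Each block gets a sum-to-zero
constraint, so **effects are reported relative to their own
(unweighted) block mean** — the reference is the block mean, not a
designated reference level; output metadata records this convention.

**Interaction.** When enabled, the 4 × 3 category lattice carries a
two-dimensional ICAR prior (rank deficiency 1, sum-to-zero).

**Hyperpriors.** Gamma(a=1, b=5e-5) on each precision (log-scale
penalty), flat on ρ; used only by the empirical-Bayes marginal
likelihood.

## Fitting

Inner loop: Newton ascent of the joint log posterior over all latents.
Feasibility (`C u = 0`) is maintained exactly — the start point is
zero and each Newton step is projected by the conditioning-by-kriging
correction, which yields the exact equality-constrained Newton step.
The Hessian is regularized with `c·CᵀC` (exact on the constraint
manifold) so a single Cholesky factorization serves the step, the
constraint correction and, at the mode, the posterior covariance

`Σ = H⁻¹ − H⁻¹Cᵀ(CH⁻¹Cᵀ)⁻¹CH⁻¹.`

Backtracking line search guards the ascent; convergence is declared
when the step's max-norm falls below `tol` (default 1e-9, which
delivers ~1e-9 accuracy in the mode thanks to quadratic convergence).
Posterior standard deviations come from `diag(Σ)` (triangular
inversion of the Cholesky factor plus the constraint correction);
covariances of arbitrary linear functionals — effect contrasts,
window-averaged fields — are computed exactly from the stored factor.
Non-convergence and a non-PD Hessian on the constraint subspace raise
errors carrying diagnostics.

Outer loop (optional, off by default): hyperparameters chosen by
maximizing the Laplace-approximate marginal likelihood over a
configured grid, with warm starts. Constrained log-determinants use
the identity `logdet(BᵀMB) = logdet(M_reg) + logdet(C M_reg⁻¹ Cᵀ) −
logdet(C Cᵀ)` for any orthonormal null-space basis `B`, so no explicit
basis is ever built.

Uncertainty is the pure Gaussian approximation — no simplified-Laplace
correction. With the moderate-to-large Poisson counts of this setting
(hundreds of negatives per cell) the latent posterior is very close to
Gaussian; an independence Metropolis–Hastings cross-check
(`mcmc_crosscheck`, proposing from the fitted Gaussian and accepting
with the exact posterior) is provided for validation and exercised on
a small instance in the tests, but is off in every pipeline.

## Reporting surfaces

* **Effect curves** (`effect_summary`): per level, posterior mean ±
  1.96 sd on the log scale, transformed monotonically to percent
  relative risk `100·(exp(·)−1)`, plus the occupancy histogram of
  cells per level and a significance flag (interval excludes zero).
* **Event contrast** (`rr_difference`): per region, Δ = mean posterior
  log relative risk over the during-window weeks minus the
  before-window weeks. The contrast includes the covariate-effect
  coordinates weighted by their window occupancy (the intercept
  cancels); its variance is propagated through the full Gaussian
  covariance of all involved coordinates within one joint fit — not
  two separate period fits — so the uncertainty of the difference is
  coherent. The significance flag marks 95% intervals excluding zero.

Weeks are 7-day bins anchored at the study origin (default
2019-01-01), not ISO calendar weeks; with this origin the three 28-day
event windows (before 2021-05-25…06-21, during 06-22…07-19, after
07-20…08-16) align exactly with week boundaries 125–128 / 129–132 /
133–136. Window membership is inclusive on both endpoints.

## Synthetic-data generator

The generator is the package's test bed: it draws a study with known
truth from the model's own generative form.

* **Region graph**: either lattices with random diagonal augmentation
  (`make_region_graph`) or the 13 merged German federal states with
  their true border adjacency (`germany_graph`; Berlin→Brandenburg,
  Bremen→Niedersachsen, Hamburg→Schleswig-Holstein — the last merge is
  a choice, Hamburg borders two states).
* **Climate**: temperature is a yearly sinusoid (peak late July) plus
  a small persistent regional offset and weekly noise, clipped to
  [−1, 24] °C; precipitation is right-skewed gamma noise clipped to
  [0, 0.07], with event cells boosted by +0.035 before clipping so
  they land in the high category. Clipping (not rejection) keeps cell
  counts deterministic.
* **Exposures**: negative-binomial weekly totals (dispersion k=5,
  configurable mean; zeros resampled unless explicitly allowed) —
  heavy-tailed, like real tweet volumes.
* **Counts**: `NTw ~ Poisson(exp(intercept)·TTW·exp(field + effects +
  event))` with the field drawn exactly from the constrained
  space–time GMRF via the Kronecker eigendecomposition. The rare draw
  with `NTw > TTW` is redrawn (the real pipeline counts negatives
  among totals, so `0 ≤ NTw ≤ TTW` must hold); redraws are counted in
  a logged warning. Expected counts above 1e7 per cell abort.
* **Truth defaults**: baseline negative share `exp(intercept) = 0.10`;
  `f_temp = (0, −0.005, 0, +0.020)` and `f_precip = (−0.0025, 0,
  +0.011)` on the log-RR scale — the ±0.5…2% magnitudes a study of
  this kind reports; event effect `log(1.10)` over 4 contiguous weeks
  in a contiguous 4-region block. The truth vectors need not sum to
  zero: a common shift is absorbed by the intercept, so recovery is
  assessed against the mean-centred truth (matching the fitted
  blocks' sum-to-zero convention).

**Field scale (a deliberate design choice).** The generator's
residual field uses `field_tau = 2500`, `ρ = 0.7`, i.e. a marginal sd
of ≈2% — a *quiet* background in which covariate effects and the
event dominate, consistent with event-contrast maps that light up
only around the event rather than everywhere. The fitter's default
field precision is instead weakly informative (`tau_field = 200`,
prior field sd ≈10%), mirroring the vague precision priors standard
in Bayesian disease mapping: an analyst does not know the residual
smoothness in advance, and a weak field prior absorbs a localized
shock with little shrinkage while leaving the covariate effects —
identified mainly through spatially common variation that the
per-week sum-to-zero constraint forbids the field to represent —
essentially untouched. Empirical Bayes would re-estimate the field
precision from the (mostly quiet) background and thereby re-shrink a
localized event bump; that is the correct global smoothness but the
wrong lens for an event contrast, which is why it is off by default.

**What the generator does not emulate**: real geography beyond
adjacency, tweet text at scale (documents are synthesized around a
small transparent lexicon), reanalysis-grid climate structure,
population weighting, and reporting artefacts (viral outliers, bots,
geotagging selection). Passing recovery tests therefore demonstrates
the statistical machinery on data from the model's own family — they
validate the estimator and pipeline, not the substantive claim on any
real corpus.

## Text pipeline

Cleaning removes URLs, @-handles, HTML tags, digits, punctuation and
symbols, lowercases, and collapses whitespace; hashtag words keep the
bare word by default (`#flut → flut`) since dropping them would
discard topical signal — a flag drops them entirely. Tokens are split
on whitespace; stopwords removed; a document is labelled negative /
positive / neutral by comparing counts of negative- and positive-
lexicon matches (terms ending `*` match as stem prefixes), with ties
— including 0–0 — neutral (symmetric and conservative). The scorer is
pluggable: any external classifier's output can be injected as
pre-labelled documents, and the statistics downstream only see labels.
Language filtering is assumed done upstream. Aggregation counts unique
documents (first occurrence of a duplicated id wins) into complete
region × week grids; out-of-window documents are skipped with a logged
count; unknown regions are an error.

## Validation scales and numerical choices

The reference synthetic study used throughout the tests is a 16-region
lattice (or the 13 German units) × 150–187 weeks with ~5000–6000
documents per region-week — the per-cell count magnitude of a
14.8M-document national corpus. Recovery checks use 20–50 replicates;
GMRF sampling laws use 50 000 draws. Dense linear algebra is used
throughout the fitter (latent dimensions up to ~2500), with one
Cholesky factorization per Newton iteration; a full fit takes a few
seconds. Eigendecompositions for sampling and generalized determinants
operate on the Kronecker factors, never on the assembled space–time
matrix. Null eigenvalues are detected at a relative threshold of 1e-9.

## Known limitations

* Hyperparameter uncertainty is not propagated (empirical Bayes point
  selection, not an INLA-style integration); interval coverage is
  validated empirically instead.
* The per-week sum-to-zero constraint means a region-block event's
  week-mean component cannot live in the field; in an event contrast
  it is recovered only through the covariate categories, which biases
  the recovered contrast slightly toward zero (visible but small in
  the recovery tests).
* The reference level for category effects is the block mean; percent
  effects are not comparable to parameterizations that pin a specific
  category at zero without re-centring.
* Real-data mode expects documents already region-assigned and
  language-filtered; geocoding and language ID are out of scope.
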