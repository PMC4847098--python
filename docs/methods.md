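# Methods

## The problem

Hospitalization counts for two aetiologically related diseases (the motivating
case is ischemic heart disease and hypertension, recorded per city
sub-district) are noisy small-area data: raw standardized hospitalization
ratios (SHR = observed / expected) are unstable wherever populations are
small, and the two diseases share unmeasured behavioural risk factors, so
information can be borrowed both across space and across diseases.  The
package implements three joint Bayesian hierarchical models over an areal
adjacency graph and the machinery to fit and compare them.

## Models

All three share the first level

    Y_di ~ Poisson(E_di * theta_di),      d = disease 1, 2;  i = area,

with expected counts `E` from internal (indirect) standardization: one pooled
rate per disease applied to each area's population, so `sum(E) = sum(Y)`
exactly.  The log relative risks are

* **Model 1 — covariate model on the SHR** (disease-1 likelihood only):
  `log theta_1i = alpha1 + beta * SHR_2i + u_1i + v_1i`.
* **Model 2 — covariate model on the structured effect**:
  `log theta_1i = alpha1 + beta1 * u_2i + u_1i + v_1i`,
  `log theta_2i = alpha2 + u_2i + v_2i`; both likelihoods enter one joint
  posterior (no "cut": disease-1 data inform `u_2` through `beta1 * u_2`).
* **Model 3 — shared component model**:
  `log theta_1i = alpha1 + delta * phi_i + u_1i + v_1i`,
  `log theta_2i = alpha2 + (1/delta) * phi_i + u_2i + v_2i`, with the
  loadings constrained to multiply to 1 via `delta = exp(log_delta)`.

Priors: flat intercepts; `beta ~ N(0, 1000)`; `log delta ~ N(0, kappa_delta)`
with `kappa_delta = 5.88` ("log-normal with mean 0 and variance kappa" is
read as the law of `log delta`, the Knorr-Held–Best convention; the constant
is exposed in `HyperParams` since the alternative readings — variance of
`delta`, or a precision — cannot be excluded from the description alone);
`u`, `phi` fields get intrinsic CAR priors; `v` fields are i.i.d.
`N(0, 1/tau_v)`; every precision gets `Gamma(0.001, 0.001)`.

## ICAR handling

The intrinsic Gaussian kernel is
`p(f|tau) ∝ tau^((n-G)/2) exp(-tau/2 * sum_{i~j} (f_i - f_j)^2)` with `G` the
number of connected components — the exponent uses the kernel's true rank
`n - G`, so maps with islands are handled correctly.  Each area's full
conditional is normal around its neighbours' mean with variance
`1/(tau * m_i)`.  Identifiability: after every sweep each ICAR field is
recentred to per-component mean zero; for a connected graph the subtracted
mean is absorbed exactly into the intercept (log theta unchanged), for a
disconnected graph the residual per-component offsets are simply projected
out, the same constraint-by-centering used by general-purpose Gibbs software.
Isolated areas carry no spatial information under ICAR and are pinned at 0.
Exact field simulation (for the generator and prior checks) draws independent
normals with variance `1/(tau*lambda_k)` on the positive-eigenvalue
Laplacian eigenvectors.

## Sampler

Metropolis-within-Gibbs: exact conjugate Gamma draws for every precision
(`Gamma(a + (n-G)/2, b + SS/2)` for ICAR fields, `Gamma(a + n/2, b + sum v^2/2)`
for the noise fields) and adaptive Gaussian random-walk Metropolis for every
other coordinate.  Three implementation choices matter:

* **Colour-block vectorization.** A greedy graph colouring partitions areas
  so no two areas in a block are adjacent; single-coordinate Metropolis moves
  within a block are then mutually independent and are executed as one
  vectorized step, bit-identical to a per-coordinate loop (asserted in the
  test suite by replaying the RNG stream through a per-site reference path).
* **Reparameterizing mixing moves**, each exactly posterior-invariant:
  a translation Gibbs move between every `v` field and its intercept
  (`c | rest ~ N(mean(v), 1/(n tau_v))`, likelihood untouched); a directional
  Metropolis move along the `(beta, alpha1)` ridge in Model 1, whose
  uncentred SHR covariate (mean ≈ 1) makes the two nearly collinear; and, for
  Model 3, an involutive mode-swap proposal `log_delta -> -log_delta` with
  `u1, u2` sheared by `±(delta - 1/delta) phi` so both predictors are
  invariant and acceptance reduces to the ICAR prior ratio.  The
  shared-component posterior genuinely has a reflected minor mode; without
  the swap, chains can stick in it and convergence diagnostics are
  misleading.  Even with it, `log_delta` mixes slowest of all parameters —
  R-hat for it can sit above 1.1 at desk-scale run lengths when the shared
  field dominates; this is a property of the model at n ≈ 60, not of the
  implementation, and longer runs resolve it.
* **Adaptation only during burn-in.** Per-coordinate step sizes are rescaled
  every `adapt_interval` sweeps toward 0.44 acceptance with a
  Robbins-Monro-decaying gain, then frozen, so the retained chain is a valid
  fixed-kernel Markov chain.

Sweep order: scalar sites, ICAR field blocks, v-field block, mixing moves,
recentring, precisions.  Chains are seeded from `SeedSequence([seed, chain])`;
runs are bitwise reproducible.  Initial values: intercepts at the log pooled
SHR mean, coefficients at 0, fields at small recentred jitter, precisions at
10, with N(0, 0.5) per-chain jitter on the scalars for overdispersion.
Default desk-scale run lengths are 3 chains x (2,000 burn-in + 5,000
retained); they are a configuration choice, not part of the model.

**Prior-only mode** (for validation) disables the likelihood.  The ICAR prior
is improper, so spatial fields are pinned at 0 and removed in this mode;
`beta`, `log delta`, `v` and `tau_v` are sampled and their prior moments
checked.  The `tau` marginal check uses `Gamma(1, 1)` hyperparameters, where
the prior mean and variance are finite and the check is informative; the
update code is identical at (0.001, 0.001).

## Summaries

* **Relative risks**: pooled-chain median and (5%, 95%) quantiles of
  `theta_di` per area; variances reported as reciprocals of the precision
  draws.
* **DIC**: `Dbar` is the posterior mean deviance (deviance includes
  `log(y!)`, the WinBUGS convention); `D(theta_bar)` plugs in the posterior
  mean of each area's *linear predictor* (log-theta scale), accumulated
  online during sampling; `pD = Dbar - D(theta_bar)`; `DIC = Dbar + pD`.
  A negative `pD` is reported as-is with a warning, never clamped.
* **Component ratio**: per retained draw, `Var_areas(c) / Var_areas(c + u + v)`
  where `c` is the cross-disease component (`beta*SHR_2`, `beta1*u_2` or
  `beta1*phi`; for Model 3 disease 2 uses `beta2*phi` against `u2 + v2`),
  with sample variances (ddof = 1) across areas and the intercept excluded
  (it is constant across areas).  The posterior median and (5%, 95%) interval
  of the draw-wise ratio are reported.  Draws with zero total variance are
  excluded and counted.  Note the ratio is not bounded by 1 draw-wise: when
  the component and the residual fields are negatively correlated across
  areas the denominator can fall below the numerator; values are reported
  unclamped.
* **Diagnostics**: classic (split-free) Gelman-Rubin PSRF from between/within
  chain variances; batch-means Monte Carlo SE with `floor(sqrt(m))` batches
  per chain, flagged against the rule MC error < 5% of the posterior SD.
* **Intercept-only baseline**: under a flat prior on `alpha`, the posterior
  of `lambda = exp(alpha)` is exactly `Gamma(sum Y, sum E)`, so the null
  model's DIC is computed from exact Gamma draws, no MCMC.

## Synthetic data

The generator emulates the shape of a city-scale two-disease hospitalization
dataset: a 6x10 rook-contiguity lattice (60 areas, comparable to a city of
~58 sub-districts), log-normal populations (median 150,000, log-SD 0.5),
pooled rates 1.5 and 1.0 per 1,000 person-years, ICAR-plus-noise log-risk
fields drawn exactly from their priors, and Poisson counts under the chosen
model structure.  Default generating values are moderate:
`alpha = 0`, `beta = 0.5` (Model 1), `beta1 = 0.7` (Model 2),
`log delta = 0.3` (Model 3), `sigma_u = 0.4`, `sigma_v = 0.2`,
`sigma_phi = 0.5`.  With a strong shared field (`sigma_phi^2 = 0.5`, unit
loadings) the two simulated SHR surfaces correlate at ~0.6, the regime these
joint models target.  For Model 1 the generator first realizes disease 2 from
a BYM structure and uses its *realized* SHR as the covariate, since that
covariate is data, not a parameter.

What the generator does **not** emulate: real map geometry (a regular
lattice has homogeneous neighbourhood structure; real contiguity graphs have
hubs and peninsulas), age structure (expected counts are one pooled rate, not
age-standardized), floating/unregistered populations, and reporting artefacts.
Passing recovery tests therefore demonstrate correctness of the machinery
under the stated model, not robustness to real-data violations of it.
Expected counts are treated as known at fit time (as when standardization is
done upstream); a flag re-standardizes from the simulated counts to mimic a
fully data-driven workflow.

## Numerical choices and edge cases

* Laplacian eigendecomposition is dense (`numpy.linalg.eigh`) and cached on
  the graph — intended for n up to a few thousand areas.
* Null-space eigenvalues are identified by a relative cutoff of 1e-9 against
  the largest eigenvalue.
* Poisson likelihood deltas use `expm1` for small shifts; proposals that
  would overflow `exp` are effectively auto-rejected by `-inf` ratios.
* A chain whose intercept becomes non-finite aborts with a diagnostic dump.
* `n_iter = 0` returns empty draws without error (useful for dry runs).
* Areas with zero observed counts are legal (SHR 0); all-zero count vectors
  make the pooled rate degenerate and are rejected at standardization.
* Asymmetric adjacency input is symmetrized with a logged warning; unknown
  labels are hard errors.

## Problem sizes used in validation

The test suite validates kernels exactly on all 771 labelled connected graphs
with up to 5 nodes, conjugacy by a 10,000-draw KS test, prior recovery on
30,000-iteration likelihood-free chains, and parameter recovery by 20
replicates per model on a 10x10 lattice at 3 chains x (2,000 + 5,000)
iterations, checking that 90% credible intervals cover the generating truth
in at least 70% of replicates (binomial slack around the nominal 90%).  The
acceptance script fits all three models on one 60-area dataset at the same
chain lengths.  These sizes were chosen as the smallest at which the checks
are statistically meaningful.

## Known limitations

* Single-site random-walk updates (plus the three reparameterizing moves) are
  adequate at n ≈ 50–100 areas but will mix slowly on much larger maps;
  a marginal or blocked field sampler would be the next step.
* `delta` (Model 3) is the slowest-mixing parameter; inspect its R-hat and
  trace before trusting its interval, and prefer longer runs for it.
* DIC's plug-in uses posterior-mean linear predictors; other plug-in
  conventions (e.g. posterior-mean hyperparameters) give slightly different
  `pD`.
* No age standardization, covariates beyond the second disease, zero
  inflation, or non-Poisson likelihoods.
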