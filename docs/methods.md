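# Methods

## The model

`stscreen` fits a Bayesian hierarchical binomial-logit model for small-area
screening-participation panels. For area `i = 1..I` and period `t = 1..T`,
with `n_it` eligible women and `Y_it` screening participants,

    Y_it ~ Binomial(n_it, theta_it)
    logit theta_it = alpha + u_i + v_i + phi_t + gamma_t + psi_it + x_it' beta

- `alpha` — overall participation level (logit scale); flat prior by
  default, optionally a proper normal.
- `u_i` — unstructured spatial heterogeneity, iid N(0, 1/tau_u).
- `v_i` — structured spatial effect with an intrinsic conditional
  autoregressive (ICAR) prior: an improper Gaussian Markov random field
  whose density penalises squared differences across the neighbourhood
  graph, `p(v | tau_v) ∝ tau_v^{(I-c)/2} exp(-tau_v/2 * sum_{i~j}(v_i - v_j)^2)`,
  with `c` the number of graph components. A hard sum-to-zero constraint
  per component identifies `alpha` (the BYM decomposition).
- `phi_t` — unstructured temporal effect, iid N(0, 1/tau_phi).
- `gamma_t` — structured temporal trend, first-order random walk
  (rank `T - 1`), hard sum-to-zero.
- `psi_it` — space-time interaction, iid N(0, 1/tau_psi) (the Type-I
  member of the standard interaction taxonomy: the written density
  `psi_it ~ N(0, tau_psi)` wins over the verbal description of which
  effects "interact").
- `beta` — coefficients of area-level covariates, vague normal
  (precision 0.001). Covariates are dichotomized at their per-period
  cross-area median and entered **centred**; centring shifts only the
  intercept, never `beta` or its odds ratio, and keeps `alpha`
  interpretable as the overall level.

Each precision carries a Gamma(shape, rate) hyperprior, stated in the
"logGamma on the log precision" convention of latent-Gaussian software —
which is exactly a Gamma prior on the precision itself. Defaults:
Gamma(1, 0.001) for `tau_u` and `tau_v`, Gamma(1, 0.01) for `tau_phi`,
Gamma(1, 0.00005) for `tau_gamma` and `tau_psi`.

Reporting follows ecological-regression practice: posterior means and
central 95% credible intervals; odds ratios as the posterior mean of
`exp(beta)` with percentile intervals ("significant" = interval excludes
1); posterior-mean odds-ratio surfaces `exp(u+v)`, `exp(phi)`,
`exp(gamma)`, `exp(psi)` (exponentiated per draw, then averaged) mapped to
`k = 5` quantile classes for choropleth display.

## Inference

Inference is by Metropolis-within-Gibbs MCMC (`stscreen.mcmc.run_mcmc`):

- **Precisions** are exact conjugate Gibbs draws,
  e.g. `tau_v | v ~ Gamma(a + (I-c)/2, b + 1/2 sum_{i~j}(v_i - v_j)^2)`,
  with the rank-based shapes for the improper ICAR/RW1 priors.
- **Latent effects** move by adaptive random-walk proposals. The iid
  blocks (`u`, `phi`, `psi`) factorize over sites, so all sites are
  proposed and accepted in parallel; the ICAR block uses graph colouring
  (same-colour sites share no edge, hence vectorize); `gamma` is updated
  site by site (`T` is small).
- **Constraints are hard and exact.** Each `v`/`gamma` move is composed
  with a re-centring whose mean is absorbed into `alpha`. Under the flat
  intercept prior on a connected graph this composite map preserves the
  constrained posterior exactly (likelihood unchanged, improper priors
  translation-invariant), so `|sum v|` and `|sum gamma|` are at floating-
  point zero after every sweep. With a proper intercept prior the shift's
  prior ratio enters the acceptance probability and the sites are updated
  sequentially; the same sequential path serves disconnected graphs.
- **Auxiliary moves** break the three empirically slow directions:
  (i) translations that exchange mass between `alpha` and the mean of each
  proper iid block (accepted on the prior ratio; the likelihood sees only
  the sum); (ii) `beta <-> u` exchanges for area-persistent covariate
  patterns; (iii) joint scale moves `(vec, tau) -> (c vec, tau/c^2)` along
  each block's variance–precision funnel, under which the conditional
  prior is invariant. All are exact Metropolis–Hastings moves.
- **Adaptation**: per-block proposal scales follow a Robbins–Monro recipe
  toward 44% acceptance, in 50-iteration batches, during burn-in only.
- **Initialization** is deterministic: `alpha` at the pooled empirical
  logit, all effects zero, precisions at their hyperprior means.
- A fixed seed yields a bit-identical chain. Draws persist as a columnar
  CSV plus a JSON sidecar (config, seed, acceptance rates, constraint
  residuals).

A `prior_only` mode disables the likelihood and draws the latent blocks
exactly from their priors given the precisions (eigen-decomposition
sampling for the ICAR, centred cumulative sums for the random walk),
leaving the precision Gibbs steps in place; the stationary precision
marginals must then equal the Gamma hyperpriors, which the test suite
checks moment-by-moment.

## Model comparison and covariate selection

`DIC = Dbar + pD`, `pD = Dbar - Dhat`, where `Dbar` is the posterior mean
deviance (binomial coefficient included, so deviances match textbook
values) and `Dhat` is the plug-in deviance at the **posterior mean of the
linear predictor** — the eta-scale convention of latent Gaussian models.
Selection is the two-stage procedure standard in this literature: each
candidate is fitted separately on top of the full spatio-temporal model
and ranked by DIC; a multivariable model then adds candidates greedily in
rank order until the DIC is no further reduced. Every fit in a screen uses
identical chain settings, with per-candidate seeds derived
deterministically from the master seed and the candidate name.
`dic_tolerance` (default 0, strict) sets how much a candidate must lower
the DIC to stay; a tolerance of 1–2 is sensible whenever the DIC itself is
Monte Carlo noisy.

**A documented limitation of DIC selection.** On panels with substantial
latent heterogeneity, an unpenalized coefficient can absorb part of the
*realized* random-effect fields (`u + v`, `psi`) at a pD discount, so
"pure noise" covariates show chance DIC improvements far more often than a
chi-square intuition suggests — in our experiments the family-wise false-
selection rate over four noise candidates was roughly one in three. The
specificity experiment in the acceptance suite therefore uses strict null
data (overall trend plus binomial noise only), where chance is the only
channel; users should treat single-covariate DIC gains of a few units on
heterogeneous data with corresponding scepticism.

## The synthetic-data generator

No registry data are deposited, so every stage runs on synthetic panels
drawn from the model's own generative structure (`stscreen.simulate`).
The default scenario emulates the published study design:

| quantity | default | rationale |
|---|---|---|
| areas `I` | 62 (2 x 31 rook lattice) | published district count; the true contiguity is not published, so any valid graph is accepted from file |
| periods `T` | 3 | three biennial invitation rounds |
| population per area | log-normal, median 4086, log-sd 0.45, constant over periods | published median eligible female population; periods average two annual populations |
| `alpha` | 0.0268 = mean period logit (level 50.7%) | with a sum-to-zero trend the intercept *is* the mean period logit; this makes the expected period rates exactly the published 48/50/54% |
| `gamma` truth | centred logits of (0.48, 0.50, 0.54) | reproduces the published rising participation pattern |
| `beta` truth | log 0.94 on one spatially clustered covariate | the published multivariable odds ratio for the leading deprivation indicator |
| `tau_u` | 100 (sd 0.10) | moderate unstructured heterogeneity |
| `tau_v` | 100 (avg marginal sd ≈ 0.17 on the default lattice) | structured clustering dominating the spatial field, ~±8pp between districts |
| `tau_phi` | 1600 (sd 0.025) | unstructured temporal noise deliberately small against the ~0.13-logit trend swing, which the study reports as the dominant temporal signal |
| `tau_psi` | 6400 (sd 0.0125) | calibrated so the covariate-free model shows roughly 90–110 effective parameters on synthetic panels (replicate mean near 95, realization sd about 11), the order reported for this model class on real panels of this size |

Covariates are generated as mixtures of an ICAR-smooth surface and white
noise (`spatial_clustering` in [0, 1]), AR(1)-correlated across periods
(0.9), then median-dichotomized — emulating spatially segregated
deprivation indicators. What the generator does **not** emulate: the
within-period annual sawtooth of invitation rounds (the analysis operates
on 2-year aggregates), non-eligibility contamination of denominators,
migration between periods, and covariate measurement error. Passing tests
therefore certify the machinery and its calibration under the model's own
assumptions, not robustness to these real-data features.

## Numerical choices

- Binomial log-likelihood via `y*eta - n*logaddexp(0, eta)`; stable for
  |eta| up to hundreds.
- ICAR simulation by eigen-decomposition of `R = D - W`, drawing normals
  with variance `1/(tau * lambda_k)` on the non-null eigenvectors — exact
  on the constraint subspace, fine for `I` up to a few hundred.
- Median dichotomization codes ties low (`> median` rule); the split is
  per period because the indicators are measured anew each period.
- Collinearity screening runs on continuous (pre-dichotomization) values;
  within an offending pair the later-listed covariate is dropped (the
  content-based choice made with real indicators is not algorithmic).
- Quantile classification places ties in the lower class, making the
  classification invariant under strictly monotone transforms; `k = 5`
  classes by default, the common choropleth convention.
- Degenerate inputs: constant covariate columns dichotomize to zero with a
  warning record; constant surfaces classify to a single class with a
  warning; an all-zero (or all-full) panel leaves the initial intercept
  undefined and is rejected with a diagnostic.

## Problem sizes used by the test and acceptance suites

Chain lengths and replicate counts are chosen as the smallest sizes at
which the corresponding statistical check is stable: 20 replicate studies
for parameter recovery (8000 iterations each) and for each selection
experiment (2600 iterations per fit), 200 short chains for the
simulation-based-calibration check on a 9-area design, 20 000 retained
draws against the quadrature oracle, and 30 000 prior-only sweeps for the
hyperprior calibration check.

## Known limitations

- Only the Type-I (iid) space-time interaction is implemented; types
  II–IV of the interaction taxonomy are out of scope.
- DIC's anti-conservatism on heterogeneous panels, discussed above.
- Random-walk MCMC is the only backend; a logistic data-augmentation
  sampler would be a drop-in alternative behind the same interface but is
  not shipped.
- The ICAR eigen-decomposition approach scales as `O(I^3)` at setup;
  adequate for city-scale lattices, not for national ones.
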