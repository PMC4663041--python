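# stscreen

Bayesian spatio-temporal small-area models for screening-participation
rates.

Organized cancer-screening programmes invite a whole population, yet
uptake varies sharply between neighbourhoods and over invitation rounds,
and the low-uptake pockets tend to coincide with socio-economic
deprivation. `stscreen` is a library for analysing such participation
panels at the small-area level: it models participant counts per district
and biennial period, separates stable spatial patterns from temporal
trends and from localized space-time departures, and screens area-level
covariates for association with non-attendance. It is aimed at spatial
epidemiologists and screening-programme evaluators; because registry
panels are rarely shareable, it also ships a first-class synthetic-data
generator that emulates a city-scale study design (62 districts, three
2-year periods, ~50% overall uptake), so the entire pipeline is testable
without any data access.

## The model

For area `i = 1..I` and period `t = 1..T`, with `n_it` eligible women and
`Y_it` participants,

    Y_it ~ Binomial(n_it, theta_it)
    logit theta_it = alpha + u_i + v_i + phi_t + gamma_t + psi_it + x_it' beta

with `u_i ~ N(0, 1/tau_u)` iid, `v_i` an intrinsic CAR (ICAR) field on the
district adjacency graph under a sum-to-zero constraint (the BYM
decomposition), `phi_t ~ N(0, 1/tau_phi)` iid, `gamma_t` a first-order
random walk (sum-to-zero), and an iid space-time interaction
`psi_it ~ N(0, 1/tau_psi)` (Knorr-Held Type I). Precisions carry Gamma
hyperpriors — Gamma(1, 0.001) for the spatial pair, Gamma(1, 0.01) for
`phi`, Gamma(1, 0.00005) for `gamma` and `psi`. Inference is by
Metropolis-within-Gibbs MCMC with conjugate precision updates and exact
hard constraints; covariates are median-dichotomized per period, screened
for collinearity (|r| > 0.8), and selected by DIC: a univariable screen
followed by greedy forward inclusion until the DIC stops improving.
Results are reported as posterior-mean odds ratios with 95% credible
intervals and quantile-classified effect surfaces. See
[docs/methods.md](docs/methods.md) for the full account.

## A worked example

```python
import numpy as np
from stscreen import (HyperpriorSpec, McmcConfig, default_scenario,
                      odds_ratio_summary, run_mcmc, simulate_study, summarize)

cfg = default_scenario(seed=42)          # 62 districts x 3 periods, OR truth 0.94
study = simulate_study(cfg)
print(np.round(study.panel.overall_rates() * 100, 2))

mc = McmcConfig(n_iterations=6000, burn_in=2000, thin=4, seed=1)
draws = run_mcmc(study.panel, cfg.graph, HyperpriorSpec(), mc,
                 X=study.design, beta_names=study.covariates.names)
orr = odds_ratio_summary(draws, "cov1")
print(f"OR {orr.mean:.3f} ({orr.q2_5:.3f}; {orr.q97_5:.3f})")
```

prints

```
[48.98 50.58 54.17]
OR 0.916 (0.895; 0.939)
```

The first line is the simulated overall participation per biennial period
in percent — the generator is calibrated so these sit near the 48/50/54
pattern of a real implementation phase. The second line is the posterior
odds ratio of the active deprivation-style covariate: districts above the
covariate median have about 8% lower odds of participation in this
realization (truth 0.94; the 95% interval is the calibrated uncertainty,
and across replicated studies it covers the truth at the nominal rate —
that calibration is part of the test suite). The `examples/` directory
walks through each capability: generating studies, fitting, DIC covariate
selection, and effect-surface reporting; a thin `stscreen` CLI
(`simulate | prep | fit | select | report`) drives the same pipeline from
the shell.

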