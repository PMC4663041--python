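"""DIC-based covariate screening and forward selection.

Simulates a study whose single true covariate has a strong effect
(odds ratio exp(-0.3) ~ 0.74) alongside four pure-noise candidates, then
runs the two-stage procedure: a univariable DIC screen, followed by greedy
forward inclusion until the DIC stops improving.  Takes a minute or two.
"""

import numpy as np

from stscreen import (
    HyperpriorSpec,
    McmcConfig,
    ScenarioConfig,
    default_scenario,
    forward_select,
    simulate_study,
    univariable_screen,
)

cfg = default_scenario(seed=7003)
cfg = ScenarioConfig(**{**cfg.__dict__, "beta": np.array([-0.3])})
study = simulate_study(cfg, n_noise_covariates=4)

hp = HyperpriorSpec()
mc = McmcConfig(n_iterations=2600, burn_in=800, thin=3, seed=100)

ranked, baseline = univariable_screen(study.panel, cfg.graph, hp, mc, study.covariates)
print(f"baseline (no covariates) DIC: {baseline.dic:.1f}")
print("univariable screen (ascending DIC):")
for entry in ranked:
    print(f"  rank {entry.rank}: {entry.name:6s} DIC {entry.dic.dic:8.1f} "
          f"OR {entry.odds_ratio.mean:.3f} ({entry.odds_ratio.q2_5:.3f}; {entry.odds_ratio.q97_5:.3f})")

selected, final, trace = forward_select(
    ranked, study.panel, cfg.graph, hp, mc, study.covariates,
    baseline=baseline, dic_tolerance=2.0,
)
print("forward selection kept:", selected or "(nothing)")
print("  'cov1' is the true covariate; its DIC sits far below the noise")
print("  candidates, which hover within Monte Carlo wiggle of the baseline.")
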