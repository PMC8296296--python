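"""Sanity check: the sampler recovers known parameters from simulated data.

A panel is drawn exactly from the model with constant coefficients
B = [[0.5, 0.1], [0.2, 0.4]], contemporaneous relation a21 = 0.3 and unit
volatility, then refit.  The posterior mean should track the flat truth and
the 90% credible band should cover it at roughly its nominal rate.
"""

import numpy as np

from tvpvarsv import (
    AdjustedPanel,
    MCMCConfig,
    ModelSpec,
    StatePaths,
    run_mcmc,
    simulate_tvpvar,
)

spec = ModelSpec(("x1", "x2"), lag=1)
init = StatePaths(np.array([[0.5, 0.1, 0.2, 0.4]]), np.array([[0.3]]),
                  np.zeros((1, 2)))
panel, truth = simulate_tvpvar(spec, init, (0.0, 0.0, 0.0), 300, seed=1)
adjusted = AdjustedPanel(panel.dates, panel.values, panel.names)

draws = run_mcmc(adjusted, spec, config=MCMCConfig(n_draws=2000, burn_in=200, seed=3))
bt = truth.state_paths.beta
bm = draws.beta.mean(axis=0)
lo = np.quantile(draws.beta, 0.05, axis=0)
hi = np.quantile(draws.beta, 0.95, axis=0)

print("true constant coefficients:", bt[0])
print("posterior mean at mid-sample:", bm[150].round(3))
print(f"share of (date, coefficient) cells within +/-0.15 of truth: "
      f"{np.mean(np.abs(bm - bt) < 0.15):.3f}")
print(f"90% credible-interval coverage of the truth: "
      f"{np.mean((bt >= lo) & (bt <= hi)):.3f}")
print("\nCoverage near 0.9 and a high within-band share say the sampler's")
print("posterior is centred and calibrated on data from the model itself.")
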