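# tvpvarsv

A time-varying-parameter vector autoregression with stochastic volatility
(TVP-VAR-SV) for daily environmental-health panels, built for studying how an
epidemic, urban mobility and air quality move together when their
relationships shift week by week. The package covers the whole workflow:
multiple imputation and previous-year seasonal adjustment of a raw daily
panel, augmented Dickey–Fuller stationarity screening, Bayesian estimation by
block Gibbs sampling, and time-varying impulse-response analysis — plus a
synthetic-data generator that draws panels exactly from the model, so every
stage is testable against known truth.

## The model

For an m-variate daily series y_t the structural system is

```
A_t y_t = M_1 y_{t-1} + ... + M_s y_{t-s} + u_t,    u_t ~ N(0, Σ_t²)
```

with A_t unit-lower-triangular (recursive identification: a variable's
structural shock moves contemporaneously only the variables ordered after
it) and Σ_t = diag(σ_1t, ..., σ_mt). Stacking the reduced-form coefficients
B_i = A_t⁻¹ M_i into β_t gives the observation equation

```
y_t = X_t β_t + A_t⁻¹ Σ_t ε_t,    ε_t ~ N(0, I_m),
X_t = I_m ⊗ (y'_{t-1}, ..., y'_{t-s})
```

where the three latent state blocks — β_t, the free lower-triangular
entries α_t of A_t, and the log-variances h_jt = ln σ_jt² — all follow
first-order random walks with diagonal innovation covariances. Priors:
β, α start at N(0, 10 I), h at N(0, 100 I); each innovation scale has a
Gamma prior on its inverse square (shape 40, rate 0.02 for the coefficient
block; 4, 0.02 for the α and h blocks). Estimation is single-chain Gibbs:
exact forward-filtering backward-sampling (FFBS) draws of β and α, an
auxiliary-mixture FFBS draw of h (10-component Gaussian approximation to
ln χ²₁), and conjugate Gamma updates of the innovation precisions; the
default configuration runs 10,000 sweeps and discards the first 1,000.

Impulse responses at date t hold that date's parameters fixed over the
horizon: ψ_0 = A_t⁻¹·diag(shock scale), ψ_k = Σ_i B_i ψ_{k-i}, reported
either at fixed horizons (1 day / 1 week / 2 weeks) across calendar time or
as full horizon curves at selected dates.

## Worked example

Simulate an m=2 panel with known constant coefficients, refit it, and check
the posterior (this is `examples/05_parameter_recovery.py`):

```python
import numpy as np
from tvpvarsv import (AdjustedPanel, MCMCConfig, ModelSpec, StatePaths,
                      run_mcmc, simulate_tvpvar)

spec = ModelSpec(("x1", "x2"), lag=1)
init = StatePaths(np.array([[0.5, 0.1, 0.2, 0.4]]), np.array([[0.3]]),
                  np.zeros((1, 2)))
panel, truth = simulate_tvpvar(spec, init, (0.0, 0.0, 0.0), 300, seed=1)
adjusted = AdjustedPanel(panel.dates, panel.values, panel.names)
draws = run_mcmc(adjusted, spec,
                 config=MCMCConfig(n_draws=2000, burn_in=200, seed=3))
```

Output:

```
true constant coefficients: [0.5 0.1 0.2 0.4]
posterior mean at mid-sample: [ 0.352 -0.074  0.212  0.416]
share of (date, coefficient) cells within +/-0.15 of truth: 0.926
90% credible-interval coverage of the truth: 0.957
```

The posterior mean tracks the flat truth (the random-walk prior shrinks the
path, so individual dates can sit a little off), 93% of all (date,
coefficient) cells are within ±0.15 of the truth, and the 90% credible band
covers the truth at close to its nominal rate — the sampler's posterior is
centred and calibrated on data drawn from the model itself.

The other scripts in `examples/` walk the remaining capabilities: the
study-like scenario generator (`01`), imputation + seasonal adjustment + the
ADF table (`02`), a full fit with convergence diagnostics (`03`), and
time-varying impulse responses (`04`). A thin CLI wraps the same pipeline:

```
tvpvarsv simulate --seed 1 --out panel.csv --baseline-out baseline.csv
tvpvarsv all --outdir report --profile fast --seed 1
```

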