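# Methods

This note records the model, the estimation machinery, the synthetic data
conditions, and the numerical and design choices behind `tvpvarsv`, at the
level of detail a maintainer or a careful user needs. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The observation equation is y_t = X_t β_t + A_t⁻¹ Σ_t ε_t with
X_t = I_m ⊗ (y'_{t-1}, …, y'_{t-s}), ε_t ~ N(0, I_m), A_t
unit-lower-triangular and Σ_t = diag(exp(h_jt/2)). The three state blocks —
β_t (m²s coefficients, plus m intercepts if enabled), α_t (the m(m−1)/2 free
entries of A_t, stacked row-major) and h_t (m log-variances) — follow
independent first-order random walks with *diagonal* innovation covariances.
The assumptions that matter:

* **Recursive identification.** Orthogonal structural shocks are obtained by
  ordering: a shock to variable j moves variables ordered before j only with
  a lag. The default ordering is (new, pas, pek) — epidemic counts first
  (treated as contemporaneously exogenous to mobility and air quality),
  mobility second, PM2.5 last. The ordering is configurable via
  `ModelSpec.names`; horizon-0 responses change with it, later horizons less
  so.
* **Diagonal innovation covariances.** State increments are mutually
  independent across components and blocks; this is what makes the
  conjugate Gamma updates per diagonal element exact.
* **No intercept by default.** The structural system carries no constant;
  seasonal adjustment is expected to have removed the level. An optional
  intercept flag exists because many applications of this model family
  include one.
* **Lag order 1 by default** for the daily three-variable system; the lag is
  a `ModelSpec` field, not hard-coded.

## Priors and their defaults

β_{s+1}, α_{s+1} ~ N(0, 10 I); h_{s+1} ~ N(0, 100 I) (diffuse on the
log-variance scale). Each innovation scale has a Gamma prior on its inverse
square, shape–rate convention: (Σβ)_i⁻² ~ Γ(40, 0.02) and
(Σα)_i⁻², (Σh)_j⁻² ~ Γ(4, 0.02). Two readings were genuinely open and are
resolved as follows: the prior is taken to apply to *precisions of
standard deviations* (the "−2" exponent), and shape–rate (not shape–scale)
is adopted — prior mean precision 2000 for the β block, i.e. prior mean
innovation SD ≈ 0.022 per day, a slowly drifting coefficient path.

## Sampler

One Gibbs sweep cycles β → α → h → variances, all conditionals exact:

* **β block.** Linear-Gaussian state space with observation covariance
  A_t⁻¹ Σ_t² A_t⁻ᵀ; drawn by covariance-form Kalman filtering plus
  Carter–Kohn backward sampling (FFBS). Filter covariances are symmetrized
  every step; any Cholesky failure gets escalating diagonal jitter (1e-10,
  1e-8, 1e-6) before raising, which in practice signals misuse (e.g.
  non-positive variances) rather than routine conditioning.
* **α block.** With ŷ_t = y_t − X_t β_t, row j of A_t ŷ_t = Σ_t ε_t makes
  ŷ_jt a regression on −ŷ_{1..j−1,t} with noise variance exp(h_jt); the
  stacked α path is then another linear-Gaussian state space and is drawn by
  the same FFBS.
* **h block.** Per series, e_jt = (A_t ŷ_t)_j is standardized to unit sample
  variance, y* = ln(ẽ² + 1e-6) linearizes the measurement, the ln χ²₁ error
  is replaced by a 10-component Gaussian mixture (the Omori–Chib–Shephard–
  Nakajima refinement; component indicators sampled given the current path),
  and a univariate FFBS draws the path; the standardization constant is
  added back. The mixture constants reproduce the exact mean (−1.27028 vs
  −1.27036) and variance (4.9337 vs π²/2 = 4.9348) of ln χ²₁; the offset
  1e-6 is absolute *after* standardization, so its distortion is uniform
  across series scales.
* **Variances.** Precision of each diagonal element ~ Γ(shape + (n−1)/2,
  rate + ½ Σ_t Δ²), n the state-path length.

Initialization: states at the prior means (zeros), variances at the
reciprocal prior-mean precisions. Explosive coefficient draws are *not*
rejected — the maximum companion-matrix spectral radius along the path is
recorded per retained draw instead, so users can see how often the posterior
visits locally unstable parameterizations (on the study-like scenario the
median is above 1; this is expected for unrestricted TVP coefficient paths
and does not destabilize the frozen-parameter impulse responses).

The FFBS recursions have two interchangeable implementations: a pure-numpy
reference and a numba-compiled core (hand-written small-matrix Cholesky and
triangular solves — at state dimensions ≤ ~10 this beats LAPACK dispatch
overhead by roughly 7×). Both paths execute the identical algorithm and
agree to machine precision; the compiled one is used when importable. The
univariate filter for the h block runs on plain Python floats for the same
overhead reason.

Defaults: 10,000 sweeps, 1,000 burn-in, thin 1, single chain
(`profile="paper"`); a `fast` profile (2,000 / 200) serves smoke runs and
the test suite.

**Known limitation.** A series with long spells at exactly zero (adjusted
epidemic counts outside the waves) drives its log-variance chain far down
and mixes slowly — inefficiency factors of order 30+ at 2,500 sweeps. The
study-scale sweep count is the mitigation; the β and α chains are unaffected.

## Diagnostics

Per monitored scalar (one representative state per block at mid-sample plus
each block's first innovation SD): autocorrelation function (default window
500), trace, kernel-density summary, Geweke convergence statistic comparing
the first 10% against the last 50% of the chain with Newey–West long-run
variances (Bartlett window, bandwidth n^(1/3) — short Geweke segments need
the smaller-than-√n bandwidth to keep the statistic's dispersion near
nominal), and the inefficiency factor 1 + 2 Σ windowed autocorrelations
(Bartlett window, bandwidth √n).

## Impulse responses

ψ_0 = A_t⁻¹ diag(shock scale), ψ_k = Σ_{i≤min(k,s)} B_i ψ_{k−i}, with date-t
parameters held fixed over the horizon (the standard convention for this
model family; integrating over future state evolution was the alternative
and is deliberately not done). The surface is the per-draw IRF averaged over
retained draws (posterior mean; 16–84% bands optional). One-standard-
deviation shock scale: by default each series' *time-average* posterior
volatility within a draw (`average_volatility`), making responses comparable
across dates; `time_t` uses the date-specific volatility. "One-day horizon"
means horizon index 1 — impact is horizon 0. Horizon cap 14 by default
(configurable; a hard guard at 120 bounds memory). Under the recursive
ordering the horizon-0 upper triangle is exactly zero; the implementation
enforces the exact zeros rather than leaving solver round-off dust.

## Preprocessing

* **Multiple imputation.** Chained equations, 10 sweeps, 5 imputations by
  default, via scikit-learn's `IterativeImputer` with `BayesianRidge` and
  posterior sampling. Each variable is regressed on the other variables'
  same-day values plus calendar covariates: day index, day-of-week
  indicators, month indicators, and a smooth local-in-time basis of Gaussian
  bumps (spacing 10 days, width 7). The smooth basis exists because month
  indicators cannot track sub-monthly level changes (epidemic waves,
  mobility suppression) and without it the imputer loses to a plain
  month-mean fill on exactly those features; value columns are z-scored
  first so one shared ridge prior treats all series and the 0/1 indicators
  comparably. The pipeline consumes the cell-wise mean of the completed
  copies (consensus); Rubin's-rules pooling of downstream uncertainty is
  out of scope. Imputed count cells are real-valued and are not rounded or
  clipped.
* **Seasonal adjustment.** value − previous-year mean of the same calendar
  month, exact cell-wise; the epidemic series carries an all-zero baseline
  (no previous-year analogue exists, consistent with a minimum of 0
  surviving adjustment). The study period is fixed to 2020-01-01 through
  2020-08-29 — 242 days.
* **Descriptives.** N, mean, min, max, sample SD (ddof = 1).

## Stationarity screen

ADF regression Δy_t = ρ y_{t−1} + Σ φ_i Δy_{t−i} + deterministic + e by OLS;
statistic = t-ratio on ρ; p-values and 1/5/10% critical values from the
MacKinnon response surfaces (statsmodels' tabulations). Three deterministic
specifications: none / constant / constant + trend. Lag cap by Schwert's
rule ⌊12 (T/100)^{1/4}⌋ (= 14 at T = 242); the augmentation order is chosen
by AIC over 0..cap on a common estimation sample (so the criteria are
comparable), then the chosen lag is re-estimated on its maximal sample —
this mirrors the reference implementation, with which the statistic agrees
to 1e-6 in the cross-validation tests. A fixed-lag mode exists for oracle
testing. Whether published tables of this kind use the cap directly or
information-criterion selection is typically unstated; AIC is the default
here.

## Synthetic data

Two generators, two purposes.

`simulate_tvpvar` draws a panel *exactly* from the model: given initial
states and per-block innovation SDs, it evolves the random walks and emits
y_t = X_t β_t + A_t⁻¹ Σ_t ε_t. The s pre-sample observations are standard
normal. With all innovation SDs zero it degenerates to a constant-parameter
homoskedastic VAR — the basis of the recovery and closed-form checks.

`make_study_like_panel` emulates the qualitative conditions of the study
data over the default 242-day calendar:

* **Epidemic counts** ("new"): two Gaussian-shaped intensity waves with
  Poisson rounding — amplitude 20 / width 10 days peaking at day 35 (early
  February) and amplitude 30 / width 6 peaking at day 165 (mid-June). These
  defaults put the daily maximum near 36 and the overall mean near 4 with
  long zero spells between waves, matching the reported descriptive scale of
  such an outbreak series.
* **Subway flow** ("pas"): a normal-year level of 1000 (units of 10⁴
  passengers) times one minus a smooth suppression curve (deep ≈85% dip
  around the first wave, ≈45% around the second), a weekend reduction of
  250/1000, and 5% lognormal noise.
* **PM2.5** ("pek"): positive, level 60 μg/m³ with a winter-high cosine
  seasonal of amplitude 25, 35% lognormal day-to-day noise.
* **Missingness**: 2% of cells at random by default (capped at 10%).
* The previous-year monthly baseline is all-zero for "new", the weekday-
  weighted level for "pas", and the month-midpoint seasonal level for "pek".

One shared seed drives independent named substreams (seed combined with a
CRC of the series name), so re-parameterizing one series never perturbs the
others. What the scenario does *not* emulate: epidemic mechanics (no
transmission model), weather covariates, holiday calendars, reporting
artifacts (batch corrections, day-of-week reporting cycles in counts), or
any true cross-series causal structure. Consequently, passing tests on this
scenario demonstrate that the pipeline's machinery is correct and robust to
realistic marginal behavior — not that the substantive findings from any
particular real dataset would replicate.

## Problem sizes in the checks

The recovery checks fit m=2, T=300 constant-parameter panels with the fast
profile, 10 seeded replicates; volatility recovery uses a single T=800
series with a sinusoidal log-variance path (amplitude 1.2, period 200 days);
ADF size/power use 2,000 Monte-Carlo replicates at T=242 in the test suite
and 600 in the acceptance script; the smoother and impulse-response oracles
run at T=30 / 100 random instances. These sizes make the full suite and the
acceptance script each complete in a few minutes on one CPU while leaving
the Monte-Carlo error comfortably inside the asserted margins.
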