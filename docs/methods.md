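# Methods

This note documents the models, numerical choices and defaults behind
`thiodose`, and what the synthetic-data experiments do and do not
demonstrate.

## Pharmacokinetic model

Three states: 6-MP in the gut `x_g` (pmol), 6-MP in plasma `x_c` (pmol) and
6-TGN in red blood cells `x_m` (pmol/8×10⁸ RBCs).  Absorption and plasma
elimination are first order (`k_ab`, `k_el`, 1/day); conversion of plasma
6-MP into 6-TGN is Michaelis–Menten with lumped rate `k_cm` (pmol/day) and
constant `K` (pmol); 6-TGN is eliminated at `k_me` (1/day).  Intracellular
6-MP is assumed to metabolize instantly (negligible intracellular pool), and
the methylated-metabolite pathway is not modelled separately — its effect
enters only through TPMT suppression of `k_cm`.

* **Bolus convention.** Oral intake is fast relative to daily dynamics, so a
  dose event adds its amount to `x_g` instantaneously.  The integrator is
  restarted at every event; an output requested exactly at an event time
  records the post-dose state.
* **Stoichiometric yield.** `ν_cm` is not separately identifiable from
  `k_cm` given `x_m` data alone; the default is `ν_cm = 1` with its units
  absorbed into `k_cm`.  It is a constructor argument for users who want an
  explicit yield.
* **Activity link.** `k_cm = k_cm,max·(1 − e/e_max)` with `e_max = 30`
  U/ml/hr (top of the modelled 7–30 activity range).  The default
  `k_cm,max = 98.5` pmol/day makes the link reproduce the population-mean
  conversion rate (39.4 pmol/day) at the mean activity of 18 U/ml/hr.  The
  link is applied once, when a rate is constructed from an activity; fitted
  `k_cm` values are always treated as effective rates.
* **Dose units.** The model works in pmol; the absolute dose scale is a free
  unit choice because no absolute bioavailability is modelled.  The standard
  generator dose of 100 pmol/day puts the mean patient's steady state
  (~283 pmol/8×10⁸ RBC) inside the therapeutic window, which is how the
  clinical standard dose behaves in the average patient.  Conversion from mg
  uses a configurable molecular weight (152.18 g/mol).

### Integration

Two paths share the event conventions and are cross-checked in the tests:

* `simulate` — adaptive LSODA with rtol 1e-8 / atol 1e-10 (configurable),
  one solver call per inter-event segment.  This is the reference path.
* `simulate_fast` — compiled fixed-step RK4 (default sub-step 0.02 day),
  used inside MCMC, variational, Sobol and MPC loops where hundreds of
  thousands of trajectory evaluations are needed.  At the default step the
  two paths agree to ~1e-5 relative on standard schedules; the system is
  only mildly stiff (time constants 0.24–12.5 days), so the explicit step is
  stable with a wide margin.

Forward sensitivity equations (for design) are integrated jointly with the
states by the same RK4 kernel and verified against central finite
differences to better than 1e-3 relative (observed ~1e-10).

## Observation model and inference

Measurements are Gaussian with SD `σ = σ_add + σ_prop·ŷ`.  The functional
form combines an assay floor with a proportional component — the standard
heteroscedastic PK error model — and both parameters are inferred with the
kinetics.

* **Priors.** The population prior over kinetics is a multivariate lognormal
  moment-matched to the natural-scale mean (4.2, 3.8, 39.4, 15.11, 0.08) and
  inter-patient covariance.  Two covariance entries required judgement: the
  printed `K` row is taken as var(K) = 111.8 (CV ≈ 70%, consistent with the
  other parameters), and var(k_me) is set to 0.003 (CV ≈ 68%).  A k_me
  variance orders of magnitude out of line with every other parameter would
  make 6-TGN elimination dominate the output variance at all late times and
  blow the population concentration band far beyond the observed 50–650
  pmol/8×10⁸ RBC spread, contradicting the sensitivity ranking this class of
  model exhibits; the adopted value keeps all five CVs commensurate.  Error
  parameters get independent weakly-informative lognormals (medians 10 and
  0.05, log-SD 0.7).
* **Box support.** Feasible ranges (e.g. `k_cm` ∈ [0.5, 500] pmol/day,
  `k_me` ∈ [0.005, 2]/day) are wide physiological boxes; the posterior never
  concentrates on a boundary in the tested regimes.
* **MCMC.** Adaptive random-walk Metropolis–Hastings on log-parameters:
  per-chain proposal covariance adapted from the chain history during
  burn-in (Haario-style) with Robbins–Monro scale tuning toward 30%
  acceptance; 4 chains, 50% burn-in, split-R̂ reported, warning outside the
  [0.05, 0.8] acceptance band.  Defaults (4000 kept draws) give R̂ ≲ 1.1 on
  sparse-data posteriors; tests that compare moments use longer runs.
* **Variational approximation.** Full-covariance Gaussian over
  log-parameters.  The evidence lower bound is maximized directly: Laplace
  initialization (mode + finite-difference Hessian), then L-BFGS on the
  reparameterized Monte-Carlo ELBO with a *whitened* antithetic base sample
  (exact empirical mean/covariance), which makes the fixed-sample ELBO exact
  for quadratic log-posteriors and prevents the variational covariance from
  overfitting base-sample noise.  Gradients are assembled analytically from
  per-point finite-difference gradients of the log-posterior.  The Gaussian
  family is biased on skewed marginals (up to ~0.3 posterior SD on `σ_add`
  under sparse data); `VBApprox.posterior_samples` therefore applies
  self-normalized importance sampling with q as the proposal, which removes
  the family bias at one posterior evaluation per draw.  Moment agreement
  with MCMC is verified at 0.2 posterior SD on a 10-observation synthetic
  patient.
* **Population and group priors.** The population prior is the mixture of
  patient posteriors with weights proportional to each patient's data count.
  It is realized by concatenating component draws with per-draw weights
  (identical mixture distribution to count-proportional resampling, with
  deterministic moments); a weighted `resample` realizes the sampling form.
  A multivariate normal fitted to the pooled draws is kept as the smooth
  reporting approximation; when a mixture prior enters MCMC/VB its density
  is evaluated as a Gaussian fit in log-space (respecting positivity).
  Group priors restrict the mixture to patients in one 2-U/ml/hr activity
  window, `(7+2(g−1), 7+2g]`, eleven groups with the top window absorbing
  activities up to 30.
* **Predictive bands and lack of fit.** Bands are shortest-interval HPDs of
  the simulated predictive (parameter draws plus one noise realization per
  draw and time).  The lack-of-fit confidence is the lower binomial tail
  `P[Bin(n, 1−level) ≤ n_outside]`: small values mean no more misses than
  chance allows (adequate when < 0.05); a band missing most points drives
  the statistic to 1.  The tail direction is a documented convention chosen
  to match both the adequacy reading of small values and the behaviour in
  gross-misfit limits.

## Sensitivity analysis and model reduction

Total Sobol indices of `x_m` are estimated with the Jansen estimator on a
scrambled-Sobol quasi-random base sample (default 1000 base points).
Indices are computed from the *independent marginals* of the population
prior: Sobol indices are defined for independent inputs, so the prior's
correlation structure is deliberately dropped and this divergence is noted
in the report.  Cumulative fixing-error bounds sum `(1+1/ε)·S_T(t)` over
six representative times (1, 10, 20, 50, 75, 100 days; ε = 0.05 gives the
per-time multiplier 21).  Parameters below 2% of the largest cumulative
bound are fixed at the population mean; among sensitive pairs with
|posterior correlation| > 0.9 only the larger-error member is estimated,
since a nearly collinear pair carries one effective degree of freedom.

With the default synthetic population prior the partition typically retains
more than one parameter above threshold (the in-cohort spread of `k_el` and
`K` is not negligible), but `k_cm` always ranks first; because a
single-sample design can identify one parameter, the offline workflow feeds
the top-ranked parameter to the design stage, and the online protocol
estimates `k_cm` only (configurable).

## Sampling-time design

For a data-less patient the robust D-optimality expectation degenerates to a
prior average, so the expected information of a single sampling day is the
weighted prior mean of `σ(t)⁻²·(∂x_m/∂k_cm)²(t)` (det of the 1×1 Fisher
matrix).  One sensitivity integration per draw covers the whole candidate
grid (default integer days 1–100).  Information accumulates toward steady
state; waiting that long delays individualization, so the selected day is
the earliest candidate within 5% of the maximum (compromise fraction
configurable, ties break to the earliest day).

## Dose control

The controller minimizes the sample-average of the squared deviation of the
daily 6-TGN trajectory from the 300 pmol/8×10⁸ RBC target over a frozen set
of 50 posterior draws, across a 75-day horizon in five 15-day blocks
(biweekly clinic visits, daily oral boluses constant within a block).
Therapeutic-window membership is checked as an output property rather than
imposed as a hard constraint — the quadratic pull to the window's interior
is the operative relaxation.  Bounds: doses in [0, 2.5×] the standard dose,
block-to-block slew within ±50% of it.  Optimization is SLSQP from three
starts (steady-state-informed, mid-box, max-dose), followed by an exact
forward projection onto the box/slew constraints, with a constant-dose
fallback; the draw set is refreshed at each visit and every seed is
recorded.  In closed loop only the leading block is applied; after each
measurement the posterior is refreshed (estimating the sensitive parameter,
the rest at population means) and the remaining horizon re-optimized from
the state of the mean-posterior model — a certainty-equivalent state
estimate, adequate because the controlled output is re-anchored by each
measurement.

## Synthetic cohorts

The generator emulates the three study designs used for model building:
D1 (23 patients, 1–4 samples within 56 days), D2 (8 patients, biweekly to
140 days), D3 (102 single activity/concentration pairs, sampled at day 28).
TPMT activities follow a truncated normal (mean 18, SD 5, range 7–30
U/ml/hr) — a unimodal spread occupying all eleven activity groups;
`k_cm` follows the activity link times a lognormal jitter with 20% CV, so
within-group heterogeneity exists (the reason concentration measurements
beat activity alone); the remaining kinetics come from the population
lognormal.  Measurement noise defaults to σ_add = 10 pmol/8×10⁸ RBC and
σ_prop = 0.05 (a realistic HPLC assay floor and CV); the magnitude is a
stated choice, not a fitted quantity, and tests vary it (including zero).
Dropout and genotype *TPMT*ᴸ/*TPMT*ᴸ patients are not simulated.

What passing tests show: the estimators are calibrated and the control loop
behaves correctly *when the data-generating process matches the model
class*.  They do not show robustness to model misspecification (RBC
lifespan dynamics, nonlinear bioavailability, adherence gaps), which real
cohorts would add.

## Recovery experiment design

The per-patient recovery experiment mirrors the online protocol: nuisance
parameters sit at the population mean in both generator and estimator, the
conversion-rate truths are drawn from the population marginal, and only
`k_cm` is estimated from 4 observations (days 7/21/35/56).  Measured
performance: mean |posterior mean − truth|/truth ≈ 5%, 95%-interval
coverage 19/20.  Under full joint 7-parameter posteriors with patients
heterogeneous in all kinetics, the `k_cm` marginal is intrinsically wider
(mean error ≈ 23% at the same design) because four points determine the
`k_cm`/`k_me` ratio much better than either factor — precisely the
collinearity that motivates the reduction step.  Joint-posterior coverage
remains calibrated (20/20 in the same experiment).

## Problem sizes used in the checks

Test and acceptance runs use cohorts of 10–23 patients, 2000–12000 MCMC
draws (2–4 chains), Sobol base samples of 256–2048, 100–300 prior draws in
design and control expectations, and 20-patient recovery experiments.
These sizes were chosen so each statistical check has comfortable margin
over its Monte-Carlo error.

## Known limitations

* Random-walk MH mixes slowly on strongly correlated, data-rich posteriors
  (split-R̂ up to ~1.3 at 20 observations with default draw counts); longer
  chains or the variational path with importance correction are the
  remedies.
* The uncorrected variational Gaussian under-covers skewed error-parameter
  marginals; use `posterior_samples` (importance-corrected) rather than
  `sample` when moments matter.
* Sobol indices ignore prior correlations by construction (documented in
  the report); rankings, not absolute index values, drive the reduction.
* The closed loop re-optimizes from a certainty-equivalent state rather
  than a per-draw state ensemble.
* Single-sample designs only; multi-point designs and A-/E-optimality are
  out of scope.
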