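# thiodose

Model-based individualized dosing of 6-mercaptopurine (6-MP), built for
pharmacometricians and control engineers studying therapeutic drug monitoring
of thiopurines.

6-MP is a prodrug: after oral intake it is absorbed from the gut, cleared
from plasma, and converted intracellularly into the cytotoxic metabolite
6-thioguanine nucleotide (6-TGN), measured in red blood cells.  The enzyme
TPMT diverts 6-MP away from the 6-TGN pathway, so patients with high TPMT
activity under-respond to a standard dose while patients with low activity
risk myelotoxicity.  Clinical practice recommends holding 6-TGN within the
therapeutic window of 235–400 pmol/8×10⁸ RBCs; `thiodose` implements a full
pipeline that individualizes the daily dose to do exactly that, using only
sparse measurements.

## The model and the workflow

Three-state kinetics (time in days, amounts in pmol):

```
dx_g/dt = −k_ab·x_g + d(t)                        gut 6-MP
dx_c/dt =  k_ab·x_g − k_el·x_c − k_cm·x_c/(K+x_c)  plasma 6-MP
dx_m/dt =  ν_cm·k_cm·x_c/(K+x_c) − k_me·x_m        RBC 6-TGN (observed)
```

with the conversion rate suppressed by relative TPMT activity,
`k_cm = k_cm,max·(1 − e/e_max)`.  Around this core the package provides:

* **Bayesian population inference** (`thiodose.inference`) — per-patient
  posteriors over `(k_ab, k_el, k_cm, K, k_me, σ_add, σ_prop)` by adaptive
  Metropolis–Hastings on log-parameters and by a variational Gaussian
  approximation (ELBO maximization, importance-corrected sampling); pooled
  population and TPMT-activity-group mixture priors weighted by each
  patient's data count; posterior-predictive HPD bands and a global
  lack-of-fit test.
* **Sensitivity-based model reduction** (`thiodose.gsa`) — Sobol total
  indices of the 6-TGN output, the probabilistic fixing-error bound
  `P[δ < (1+1/ε)·S_T] ≥ 1−ε` (multiplier 21 at ε = 0.05), and the
  sensitive/insensitive parameter partition.
* **Robust D-optimal sampling design** (`thiodose.oed`) — expected Fisher
  information over the population prior as a function of the single
  blood-sampling day, with an earliest-day-within-5%-of-maximum compromise.
* **Robust model-predictive dose control** (`thiodose.mpc`) — receding-
  horizon optimization of block-wise daily doses minimizing expected squared
  deviation from a 300 pmol/8×10⁸ RBC target over posterior draws, under
  dose box and slew constraints.
* **Synthetic cohorts** (`thiodose.synthetic_data`) — virtual patients with
  activity-linked conversion rates emulating the three literature study
  designs (23 sparse patients / 8 dense patients / 102 activity–concentration
  pairs), so the whole chain is testable without clinical data.
* **Orchestration** (`thiodose.workflow`, `thiodose` CLI) — the offline
  population phase and the online new-patient protocol (group prior until
  the design day, one measurement, individualized re-optimization).

## Worked example

```python
import numpy as np
from thiodose import (
    PKParams, DoseSchedule, simulate, steady_state,
    PosteriorSamples, ControlConfig, optimize_dose,
)

patient = PKParams(k_ab=4.2, k_el=3.8, k_cm=39.4, K=15.11, k_me=0.08)
doses = DoseSchedule.daily(amount=100.0, n_days=75)
traj = simulate(patient, doses, times=[7, 21, 35, 56, 75])
for t, xm in zip(traj.times, traj.x_m):
    print(f"day {t:3.0f}:  6-TGN = {xm:6.1f} pmol/8e8 RBC")
print(f"steady state under 100 pmol/day: {steady_state(patient, 100.0):.1f}")

rng = np.random.default_rng(0)
draws = np.exp(np.log([4.2, 3.8, 39.4, 15.11, 0.08, 10.0, 0.05])
               + 0.25 * rng.standard_normal((200, 7)))
posterior = PosteriorSamples(draws, np.ones(200))
plan = optimize_dose(posterior, ControlConfig(), seed=1)
print("block doses (pmol/day):", np.round(plan.U, 1))
print(f"predicted final-block mean: {plan.pred_mean[-15:].mean():.0f} pmol/8e8 RBC")
```

prints

```
day   7:  6-TGN =  111.4 pmol/8e8 RBC
day  21:  6-TGN =  211.9 pmol/8e8 RBC
day  35:  6-TGN =  244.7 pmol/8e8 RBC
day  56:  6-TGN =  257.6 pmol/8e8 RBC
day  75:  6-TGN =  260.0 pmol/8e8 RBC
steady state under 100 pmol/day: 282.7
block doses (pmol/day): [226.1 176.1 126.1  95.9 129.6]
predicted final-block mean: 283 pmol/8e8 RBC
```

The population-mean patient approaches ~283 pmol/8×10⁸ RBC at steady state
under the standard 100 pmol/day schedule — inside the therapeutic window but
below target — so the robust controller front-loads the dose (226 → 176 →
126 pmol/day, riding the −50 pmol/day slew limit) and then settles near a
maintenance dose that holds the predicted concentration close to the
300 pmol/8×10⁸ RBC target despite the 25% parameter uncertainty in the
posterior draws.

The same stages are scriptable from the shell:

```bash
thiodose synth --design D1 --seed 2 --out d1/
thiodose offline --data d1/ --seed 3 --out artifacts/
thiodose patient --artifacts artifacts/ --activity 12.5 --seed 4 --out patient.json
```

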