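"""Two-phase orchestration: offline population-model building and the
online protocol for a newly arriving patient.

Offline, a retrospective cohort with dosing histories and sparse 6-TGN
measurements is turned into per-patient posteriors, a pooled population
prior, a sensitivity-based parameter partition and a robust D-optimal
sampling day.  Online, a new patient is placed into a TPMT-activity group at
t = 0, dosed under the group prior until the design day, measured once, and
switched to an individualized posterior (only the sensitivity-selected
parameter is re-estimated; the rest stay at the population mean) with the
dose re-optimized by the same receding-horizon controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from . import config
from .exceptions import EmptyGroupError
from .inference import (
    Band,
    LogNormalPrior,
    MeasurementSeries,
    PopulationPrior,
    PosteriorSamples,
    build_group_prior,
    build_population_prior,
    default_prior,
    predictive_band,
    sample_posterior_mcmc,
)
from .gsa import SensitivityReport, sensitivity_report
from .mpc import ControlConfig, ControlPlan, optimize_dose
from .oed import DesignResult, expected_information_profile
from .pkmodel import DoseSchedule, PKParams, TPMTActivity, simulate_fast
from .synthetic_data import VirtualPatient, assign_activity_group, group_window

__all__ = ["OfflineArtifacts", "OnlineArtifacts", "run_offline", "run_new_patient"]


@dataclass
class OfflineArtifacts:
    """Products of the population-model building phase."""

    posteriors: list[PosteriorSamples]
    n_points: list[int]
    activities: list[float | None]
    population_prior: PopulationPrior
    gsa: SensitivityReport
    design: DesignResult
    seed: int


@dataclass
class OnlineArtifacts:
    """Products of one new-patient episode."""

    group: int
    group_prior: PosteriorSamples
    online_prior: PosteriorSamples  # sensitive parameter varies, rest at population mean
    pre_plan: ControlPlan
    measurement_day: float
    measurement: float
    posterior: PosteriorSamples
    post_plan: ControlPlan
    bands: dict[str, Band]
    seed: int


def run_offline(
    cohort: Sequence[MeasurementSeries],
    seed: int = 0,
    prior: LogNormalPrior | None = None,
    n_draws: int = 3000,
    gsa_n_base: int = 512,
    candidate_days: Sequence[float] | None = None,
    reference_doses: DoseSchedule | None = None,
    mcmc_chains: int = 4,
) -> OfflineArtifacts:
    """Run the full offline chain: posteriors -> population prior -> GSA -> design.

    The GSA partition feeds the design's parameter subset.  Deterministic for
    a fixed seed and cohort.
    """
    if len(cohort) < 2:
        raise ValueError("offline phase needs at least 2 patients")
    prior = prior or default_prior()
    rng = np.random.default_rng(seed)
    posteriors = []
    for series in cohort:
        try:
            posteriors.append(
                sample_posterior_mcmc(
                    series,
                    prior,
                    n_draws=n_draws,
                    seed=int(rng.integers(2**31 - 1)),
                    n_chains=mcmc_chains,
                )
            )
        except Exception as exc:  # pragma: no cover - stage labeling
            raise RuntimeError(f"posterior stage failed for {series.patient_id}") from exc
    n_points = [s.n_obs for s in cohort]
    activities = [s.activity.e if s.activity else None for s in cohort]
    pop = build_population_prior(posteriors, n_points)
    doses = reference_doses or DoseSchedule.daily(config.STANDARD_DAILY_DOSE, 100)
    gsa = sensitivity_report(pop, doses, n_base=gsa_n_base, seed=seed + 1)
    days = np.asarray(candidate_days if candidate_days is not None else np.arange(1.0, 101.0))
    # a single-sample design can identify one parameter: use the dominant one
    top = max(gsa.estimate, key=lambda n: gsa.bounds[n])
    design = expected_information_profile(
        pop, days, doses, param_subset=(top,), n_draws=200, seed=seed + 2
    )
    return OfflineArtifacts(posteriors, n_points, activities, pop, gsa, design, seed)


def _online_prior(
    offline: OfflineArtifacts, group_prior: PosteriorSamples, estimate: Sequence[str]
) -> tuple[PosteriorSamples, dict[str, float]]:
    """Prior for the new patient: estimated parameters from the group mixture,
    all other parameters pinned exactly at the population mean."""
    names = offline.population_prior.names
    mean = offline.population_prior.mvn_mean
    draws = np.tile(mean, (group_prior.draws.shape[0], 1))
    for name in estimate:
        draws[:, names.index(name)] = group_prior.param(name)
    fixed = {
        n: float(mean[names.index(n)]) for n in names if n not in estimate
    }
    prior = PosteriorSamples(
        draws, group_prior.weights, {"kind": "group", "reduced": True}
    )
    return prior, fixed


def run_new_patient(
    activity: TPMTActivity,
    offline: OfflineArtifacts,
    true_patient: VirtualPatient,
    cfg: ControlConfig | None = None,
    seed: int = 0,
    n_mcmc: int = 2000,
    band_times: Sequence[float] | None = None,
    estimate: Sequence[str] = ("k_cm",),
) -> OnlineArtifacts:
    """Simulate the online protocol for one (virtual) new patient.

    The patient is grouped by TPMT activity at t = 0 and dosed under the
    group prior until the offline design day; the single 6-TGN measurement
    taken that day updates the sensitive-parameter posterior, after which the
    remaining horizon is re-optimized.  ``true_patient`` supplies the
    simulation ground truth and measurement noise.
    """
    cfg = cfg or ControlConfig()
    rng = np.random.default_rng(seed)
    group = assign_activity_group(activity.e)
    try:
        group_prior = build_group_prior(
            offline.posteriors, offline.activities, offline.n_points, group_window(group)
        )
    except EmptyGroupError:
        warnings.warn(
            f"activity group {group} empty in the cohort; falling back to the "
            "population prior",
            stacklevel=2,
        )
        group_prior = offline.population_prior.as_samples()
    online_prior, fixed = _online_prior(offline, group_prior, tuple(estimate))

    t_star = offline.design.chosen_time
    # round the design day onto the controller's block grid
    t_meas = float(np.clip(np.ceil(t_star / cfg.block) * cfg.block, cfg.block, cfg.horizon - cfg.block))

    pre_plan = optimize_dose(online_prior, cfg, seed=seed)
    daily = pre_plan.daily_doses()
    di = int(t_meas)
    applied = DoseSchedule(tuple((float(i), float(daily[i])) for i in range(di)))
    truth = simulate_fast(true_patient.params, applied, np.array([t_meas])).x_m[0]
    sigma = true_patient.err.sigma_add + true_patient.err.sigma_prop * max(truth, 0.0)
    y = max(truth + sigma * rng.standard_normal(), 0.0)

    series = MeasurementSeries(
        true_patient.patient_id, np.array([t_meas]), np.array([y]), applied, activity
    )
    prior_density = LogNormalPrior.from_draws(
        online_prior.names, online_prior.draws, online_prior.weights
    )
    posterior = sample_posterior_mcmc(
        series,
        prior_density,
        n_draws=n_mcmc,
        seed=int(rng.integers(2**31 - 1)),
        estimate=tuple(estimate),
        fixed=fixed,
        n_chains=2,
    )

    remaining = cfg.horizon - di
    sub_cfg = ControlConfig(
        setpoint=cfg.setpoint, window=cfg.window, horizon=remaining, block=cfg.block,
        u_min=cfg.u_min, u_max=cfg.u_max, du_min=cfg.du_min, du_max=cfg.du_max,
        n_samples=cfg.n_samples, nu_cm=cfg.nu_cm,
    )
    mean_theta = posterior.mean()[:5]
    state = simulate_fast(
        PKParams.from_theta(mean_theta, nu_cm=cfg.nu_cm), applied, np.array([t_meas])
    )
    x_now = np.array([state.x_g[0], state.x_c[0], state.x_m[0]])
    post_plan = optimize_dose(
        posterior, sub_cfg, u_prev=float(daily[di - 1]), seed=seed + 1, x0=x_now
    )

    bt = np.asarray(band_times if band_times is not None else np.arange(5.0, 76.0, 5.0))
    doses_ref = DoseSchedule.daily(config.STANDARD_DAILY_DOSE, int(bt.max()) + 1)
    bands = {
        "population": predictive_band(
            offline.population_prior.as_samples(), doses_ref, bt, seed=seed + 11
        ),
        "group": predictive_band(online_prior, doses_ref, bt, seed=seed + 12),
        "patient": predictive_band(posterior, doses_ref, bt, seed=seed + 13),
    }
    return OnlineArtifacts(
        group, group_prior, online_prior, pre_plan, t_meas, float(y),
        posterior, post_plan, bands, seed,
    )
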