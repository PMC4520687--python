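"""Virtual patients and synthetic datasets with the structure of the three
literature cohorts used for 6-MP therapeutic drug monitoring studies:

* ``D1`` — 23 patients, at most four 6-TGN measurements each within 8 weeks;
* ``D2`` — 8 patients measured biweekly over 20 weeks;
* ``D3`` — 102 patients with one TPMT-activity / 6-TGN pair each, activities
  spanning 7-30 U/ml/hr.

Patient kinetics are drawn from a moment-matched multivariate lognormal
population; each patient's conversion rate is tied to their TPMT activity
through the suppression law k_cm = k_cm_max * (1 - e/e_max) with
multiplicative lognormal jitter, so within-activity-group heterogeneity
exists by construction.  Observations are model simulations plus
additive-plus-proportional Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import config
from ._stats import ensure_pd
from .inference import ErrorParams, LogNormalPrior, MeasurementSeries
from .pkmodel import (
    DoseSchedule,
    PKParams,
    TPMTActivity,
    effective_conversion_rate,
    simulate_fast,
)

__all__ = [
    "PopulationStats",
    "VirtualPatient",
    "sample_population",
    "sample_activity",
    "assign_activity_group",
    "genotype_from_activity",
    "make_virtual_patient",
    "generate_dataset",
]

N_GROUPS = 11
GROUP_ANCHOR = 7.0  # groups are (7 + 2(g-1), 7 + 2g], capped at group 11
GROUP_WIDTH = 2.0


@dataclass(frozen=True)
class PopulationStats:
    """Natural-scale mean and covariance of (k_ab, k_el, k_cm, K, k_me)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.mean.shape != (5,) or self.cov.shape != (5, 5):
            raise ValueError("expected 5 parameters")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    @classmethod
    def default(cls) -> "PopulationStats":
        return cls(config.population_mean(), config.population_cov())

    def lognormal(self) -> LogNormalPrior:
        return LogNormalPrior.from_moments(config.PK_PARAM_NAMES, self.mean, self.cov)


@dataclass(frozen=True)
class VirtualPatient:
    """Ground truth for one simulated patient."""

    patient_id: str
    params: PKParams
    err: ErrorParams
    activity: TPMTActivity
    group: int
    genotype: Literal["heterozygous", "homozygous-high"]


def sample_population(
    n: int, stats: PopulationStats | None = None, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` kinetic parameter vectors from the population distribution.

    The population is a multivariate lognormal moment-matched to the
    natural-scale statistics, so every draw is positive and the large-sample
    mean/covariance reproduce ``stats``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    stats = stats or PopulationStats.default()
    return stats.lognormal().sample(n, np.random.default_rng(seed))


def sample_activity(n: int, gen: config.GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """TPMT activities from a truncated normal on the observed range."""
    lo, hi = gen.activity_range
    a = (lo - gen.activity_mean) / gen.activity_sd
    b = (hi - gen.activity_mean) / gen.activity_sd
    return truncnorm.rvs(
        a, b, loc=gen.activity_mean, scale=gen.activity_sd, size=n, random_state=rng
    )


def assign_activity_group(e: float) -> int:
    """Activity-window group id in 1..11.

    Windows are 2-unit half-open intervals (7 + 2(g-1), 7 + 2g] — the lower
    edge is exclusive — with the top window absorbing activities up to the
    maximum (30 U/ml/hr), so ids stay within 1..11.
    """
    if e <= GROUP_ANCHOR:
        raise ValueError(f"activity {e} at or below the modeled range (> {GROUP_ANCHOR})")
    g = int(np.ceil((e - GROUP_ANCHOR) / GROUP_WIDTH))
    return min(g, N_GROUPS)


def group_window(g: int) -> tuple[float, float]:
    """(lo, hi] activity window of group ``g``; the top group extends to e_max."""
    if not 1 <= g <= N_GROUPS:
        raise ValueError("group id must be in 1..11")
    lo = GROUP_ANCHOR + GROUP_WIDTH * (g - 1)
    hi = GROUP_ANCHOR + GROUP_WIDTH * g if g < N_GROUPS else config.E_MAX
    return lo, hi


def genotype_from_activity(e: float) -> str:
    """TPMT genotype class from activity: below 10 U/ml/hr -> heterozygous.

    Activities of exactly 10 are classed homozygous-high by convention (the
    boundary itself is not assigned by the activity rule).
    """
    if e <= 0:
        raise ValueError("activity must be positive")
    return "heterozygous" if e < 10.0 else "homozygous-high"


def make_virtual_patient(
    patient_id: str,
    activity: float,
    stats: PopulationStats,
    gen: config.GeneratorConfig,
    rng: np.random.Generator,
) -> VirtualPatient:
    """Sample one patient: kinetics from the population, k_cm from activity.

    (k_ab, k_el, K, k_me) come from the corresponding marginal block of the
    population lognormal; k_cm follows the activity suppression law times a
    lognormal jitter with CV ``gen.kcm_jitter_cv`` — phenotype varies within
    an activity level, which is precisely why concentration measurements beat
    activity alone.
    """
    act = TPMTActivity(activity, gen.e_max, gen.k_cm_max)
    ln = stats.lognormal()
    idx = [0, 1, 3, 4]  # k_ab, k_el, K, k_me
    sub = LogNormalPrior(
        [config.PK_PARAM_NAMES[i] for i in idx],
        ln.log_mu[idx],
        ln.log_cov[np.ix_(idx, idx)],
    )
    k_ab, k_el, K, k_me = sub.sample(1, rng)[0]
    s2 = np.log1p(gen.kcm_jitter_cv**2)
    jitter = np.exp(rng.standard_normal() * np.sqrt(s2) - 0.5 * s2)
    k_cm = max(effective_conversion_rate(act) * jitter, 1e-6)
    # a zero-noise generator still needs a valid (not-all-zero) error model
    err = (
        ErrorParams(gen.sigma_add, gen.sigma_prop)
        if gen.sigma_add > 0 or gen.sigma_prop > 0
        else ErrorParams(1e-12, 0.0)
    )
    return VirtualPatient(
        patient_id=patient_id,
        params=PKParams(k_ab, k_el, k_cm, K, k_me),
        err=err,
        activity=act,
        group=assign_activity_group(activity),
        genotype=genotype_from_activity(activity),
    )


def _observe(
    patient: VirtualPatient,
    gen: config.GeneratorConfig,
    doses: DoseSchedule,
    times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    xm = simulate_fast(patient.params, doses, times).x_m
    if gen.sigma_add == 0 and gen.sigma_prop == 0:
        return np.clip(xm, 0.0, None)
    sigma = gen.sigma_add + gen.sigma_prop * np.clip(xm, 0.0, None)
    return np.clip(xm + sigma * rng.standard_normal(times.size), 0.0, None)


def generate_dataset(
    design: Literal["D1", "D2", "D3"],
    stats: PopulationStats | None = None,
    gen: config.GeneratorConfig | None = None,
    seed: int = 0,
    n_obs_range: tuple[int, int] | None = None,
) -> tuple[list[MeasurementSeries], list[VirtualPatient]]:
    """Emulate one of the three study designs.

    Every patient receives the standard constant daily bolus from day 0.
    ``n_obs_range`` overrides the per-patient observation count of D1
    (default 1-4, weighted toward richer series).  Setting the generator's
    noise to zero makes observations equal the model simulation exactly.
    """
    stats = stats or PopulationStats.default()
    gen = gen or config.GeneratorConfig()
    rng = np.random.default_rng(seed)
    series: list[MeasurementSeries] = []
    patients: list[VirtualPatient] = []

    def schedule(n_days: int) -> DoseSchedule:
        return DoseSchedule.daily(gen.daily_dose, n_days)

    if design == "D1":
        lo, hi = n_obs_range or (1, 4)
        if not 1 <= lo <= hi <= 4:
            raise ValueError("D1 observation counts must lie in 1..4")
        counts = rng.choice(np.arange(lo, hi + 1), size=23)
        activities = sample_activity(23, gen, rng)
        for i in range(23):
            p = make_virtual_patient(f"D1-{i+1:02d}", activities[i], stats, gen, rng)
            times = np.sort(rng.choice(np.arange(7.0, 57.0), size=counts[i], replace=False))
            doses = schedule(56)
            y = _observe(p, gen, doses, times, rng)
            series.append(MeasurementSeries(p.patient_id, times, y, doses, p.activity))
            patients.append(p)
    elif design == "D2":
        activities = sample_activity(8, gen, rng)
        times = np.arange(14.0, 141.0, 14.0)
        doses = schedule(140)
        for i in range(8):
            p = make_virtual_patient(f"D2-{i+1:02d}", activities[i], stats, gen, rng)
            y = _observe(p, gen, doses, times, rng)
            series.append(MeasurementSeries(p.patient_id, times, y, doses, p.activity))
            patients.append(p)
    elif design == "D3":
        activities = sample_activity(102, gen, rng)
        times = np.array([28.0])  # single TDM sample at four weeks
        doses = schedule(28)
        for i in range(102):
            p = make_virtual_patient(f"D3-{i+1:03d}", activities[i], stats, gen, rng)
            y = _observe(p, gen, doses, times, rng)
            series.append(MeasurementSeries(p.patient_id, times, y, doses, p.activity))
            patients.append(p)
    else:
        raise ValueError(f"unknown design {design!r}")
    return series, patients


def dataset_to_frames(series: Sequence[MeasurementSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(measurements, dose events) tables in the package CSV schema."""
    meas = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "time_day": t,
                "y_pmol_per_8e8RBC": y,
                "activity_U_ml_hr": s.activity.e if s.activity else np.nan,
            }
            for s in series
            for t, y in zip(s.times, s.y)
        ]
    )
    doses = pd.DataFrame(
        [
            {"patient_id": s.patient_id, "time_day": t, "amount_pmol": a}
            for s in series
            for t, a in s.doses.events
        ]
    )
    return meas, doses


def frames_to_dataset(
    meas: pd.DataFrame, doses: pd.DataFrame
) -> list[MeasurementSeries]:
    """Rebuild measurement series from the CSV schema tables."""
    out = []
    for pid, grp in meas.groupby("patient_id", sort=False):
        dgrp = doses[doses["patient_id"] == pid].sort_values("time_day")
        sched = DoseSchedule(
            tuple(zip(dgrp["time_day"].tolist(), dgrp["amount_pmol"].tolist()))
        )
        act = None
        if "activity_U_ml_hr" in grp and np.isfinite(grp["activity_U_ml_hr"].iloc[0]):
            act = TPMTActivity(float(grp["activity_U_ml_hr"].iloc[0]))
        grp = grp.sort_values("time_day")
        out.append(
            MeasurementSeries(
                str(pid),
                grp["time_day"].to_numpy(float),
                grp["y_pmol_per_8e8RBC"].to_numpy(float),
                sched,
                act,
            )
        )
    return out
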