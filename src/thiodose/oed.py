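"""Robust D-optimal choice of the blood-sampling day.

For a new patient no data exist yet, so the design is made robust by
averaging the determinant of the Fisher information matrix over draws from
the population (or group) prior.  The design space is a single sampling day
on an integer grid; the information carried by a measurement at time t for
the estimated parameter subset is

    I(t) = sigma(t)^-2 * s(t) s(t)^T,   s(t) = d xm / d theta_hat |_t

with sigma(t) = sigma_add + sigma_prop * xm(t).  Because waiting for the
absolute maximum (near steady state) delays individualization, the selected
day is the earliest candidate whose expected information is within a small
compromise fraction of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import config
from ._ode import rk4_sensitivities
from .exceptions import IntegrationError
from .inference import ErrorParams, PopulationPrior, PosteriorSamples
from .pkmodel import DoseSchedule, PKParams

__all__ = [
    "DesignResult",
    "output_sensitivities",
    "fisher_information",
    "expected_information_profile",
    "select_sampling_time",
]

_PK_IDX = {n: i for i, n in enumerate(config.PK_PARAM_NAMES)}


@dataclass(frozen=True)
class DesignResult:
    """Expected-information profile over candidate sampling days."""

    candidate_times: np.ndarray
    expected_information: np.ndarray
    chosen_time: float
    compromise_fraction: float
    param_subset: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.candidate_times,
                "expected_information": self.expected_information,
            }
        )


def output_sensitivities(
    params: PKParams,
    doses: DoseSchedule,
    times: Sequence[float],
    param_subset: Sequence[str] = ("k_cm",),
    h: float = config.FAST_STEP,
) -> np.ndarray:
    """Sensitivities d xm/d theta at each time, via forward sensitivity ODEs.

    Returns an (n_times, n_subset) matrix.  The sensitivity equations are
    integrated jointly with the states, so the derivatives share the
    integrator's accuracy (they are cross-checked against central finite
    differences in the test-suite).
    """
    if not param_subset:
        raise ValueError("param_subset must be non-empty")
    times = np.asarray(times, dtype=float)
    dt_ev, da_ev = doses.arrays()
    states, sens = rk4_sensitivities(
        params.theta(), params.nu_cm, np.zeros(3), dt_ev, da_ev,
        doses.infusion, times, h,
    )
    if not np.all(np.isfinite(sens)):
        raise IntegrationError("non-finite sensitivities")
    cols = [_PK_IDX[name] for name in param_subset]
    return sens[:, 2, cols]


def predicted_xm(
    params: PKParams,
    doses: DoseSchedule,
    times: Sequence[float],
    h: float = config.FAST_STEP,
) -> np.ndarray:
    from .pkmodel import simulate_fast

    return simulate_fast(params, doses, times, h=h).x_m


def fisher_information(
    S: np.ndarray, err: ErrorParams, predictions: np.ndarray
) -> np.ndarray:
    """Fisher information of the measurement set: sum_t sigma_t^-2 s_t s_t'."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    yhat = np.asarray(predictions, dtype=float)
    if S.shape[0] != yhat.size:
        raise ValueError("one sensitivity row per measurement is required")
    sigma = err.sigma_add + err.sigma_prop * np.clip(yhat, 0.0, None)
    if np.any(sigma <= 0):
        raise ValueError("error SD must be positive at every measurement")
    W = S / sigma[:, None]
    return W.T @ W


def expected_information_profile(
    prior: PosteriorSamples | PopulationPrior,
    candidate_times: Sequence[float],
    doses: DoseSchedule,
    param_subset: Sequence[str] = ("k_cm",),
    n_draws: int = 200,
    seed: int = 0,
    compromise_fraction: float = 0.05,
    h: float = config.FAST_STEP,
) -> DesignResult:
    """Average det(I) over prior draws for each single-sample candidate day.

    For a data-less patient the likelihood weighting of the robust design
    criterion degenerates to the prior itself, so the expectation is a
    plain (weighted) prior average.  One sensitivity integration per draw
    covers all candidate days.
    """
    candidate_times = np.asarray(candidate_times, dtype=float)
    if candidate_times.size == 0:
        raise ValueError("candidate set must be non-empty")
    if isinstance(prior, PopulationPrior):
        prior = prior.as_samples()
    rng = np.random.default_rng(seed)
    draws = prior.resample(n_draws, rng)
    dt_ev, da_ev = doses.arrays()
    k = len(param_subset)
    cols = [_PK_IDX[n] for n in param_subset]
    profile = np.zeros(candidate_times.size)
    for row in draws:
        states, sens = rk4_sensitivities(
            row[:5], 1.0, np.zeros(3), dt_ev, da_ev, doses.infusion,
            candidate_times, h,
        )
        yhat = states[:, 2]
        sigma = row[5] + row[6] * np.clip(yhat, 0.0, None)
        s = sens[:, 2, cols] / sigma[:, None]
        if k == 1:
            dets = (s[:, 0]) ** 2
        else:
            dets = np.array(
                [np.linalg.det(np.outer(s[t], s[t])) for t in range(candidate_times.size)]
            )
        profile += dets / n_draws
    chosen = select_sampling_time_from_arrays(
        candidate_times, profile, compromise_fraction
    )
    return DesignResult(
        candidate_times, profile, chosen, compromise_fraction, tuple(param_subset)
    )


def select_sampling_time_from_arrays(
    times: np.ndarray, info: np.ndarray, fraction: float = 0.05
) -> float:
    """Earliest candidate whose information is within ``fraction`` of the max."""
    times = np.asarray(times, dtype=float)
    info = np.asarray(info, dtype=float)
    if times.size == 0:
        raise ValueError("empty profile")
    cutoff = (1.0 - fraction) * info.max()
    ok = np.nonzero(info >= cutoff)[0]
    return float(times[ok[0]])


def select_sampling_time(profile: DesignResult, compromise_fraction: float = 0.05) -> float:
    """Re-select the sampling day from an existing profile."""
    return select_sampling_time_from_arrays(
        profile.candidate_times, profile.expected_information, compromise_fraction
    )
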