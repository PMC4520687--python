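"""Package-wide defaults and unit constants.

All quantities are in the model's working units: time in days, 6-MP amounts
in pmol, 6-TGN concentration in pmol per 8e8 red blood cells, TPMT activity
in U/ml/hr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: molecular weight of 6-mercaptopurine, g/mol (used only for mg <-> pmol
#: conversion of externally supplied doses; the model itself works in pmol).
MW_6MP = 152.18

#: maximum TPMT activity, U/ml/hr (top of the observed 7-30 range).
E_MAX = 30.0

#: maximal 6-MP -> 6-TGN conversion rate, pmol/day.  Chosen so that the
#: activity link k_cm = k_cm_max * (1 - e/E_MAX) reproduces the population
#: mean conversion rate (39.4 pmol/day) at the population mean activity
#: (18 U/ml/hr): 98.5 * (1 - 18/30) = 39.4.
K_CM_MAX = 98.5

#: therapeutic 6-TGN window, pmol/8e8 RBCs.
THERAPEUTIC_WINDOW = (235.0, 400.0)

#: 6-TGN concentration target used by the dose controller, pmol/8e8 RBCs.
TARGET_CONCENTRATION = 300.0

#: standard daily oral 6-MP dose used by the synthetic cohort generator,
#: pmol/day.  The absolute dose scale is a free unit choice of the model;
#: this value puts the mean patient's steady-state 6-TGN (~262) inside the
#: therapeutic window under once-daily dosing.
STANDARD_DAILY_DOSE = 100.0

#: measurement error defaults for the synthetic generator: additive floor
#: (pmol/8e8 RBCs) and proportional component (typical HPLC assay CV).
SIGMA_ADD = 10.0
SIGMA_PROP = 0.05

#: canonical parameter ordering used across the package.
PK_PARAM_NAMES = ("k_ab", "k_el", "k_cm", "K", "k_me")
ERROR_PARAM_NAMES = ("sigma_add", "sigma_prop")
ALL_PARAM_NAMES = PK_PARAM_NAMES + ERROR_PARAM_NAMES

#: default fixed sub-step (days) of the fast RK4 path.
FAST_STEP = 0.02

#: times (days) at which cumulative sensitivity errors are accumulated.
GSA_TIMES = (1.0, 10.0, 20.0, 50.0, 75.0, 100.0)


def population_mean() -> np.ndarray:
    """Population mean of (k_ab, k_el, k_cm, K, k_me)."""
    return np.array([4.2, 3.8, 39.4, 15.11, 0.08])


def population_cov() -> np.ndarray:
    """Inter-patient covariance of (k_ab, k_el, k_cm, K, k_me), natural scale.

    The k_me variance is set to 0.003 (SD 0.055, CV ~68%), in line with the
    40-70% coefficients of variation of the other four parameters and with
    the observed population spread of steady-state 6-TGN; see docs/methods.md
    for the rationale behind this default.
    """
    return np.array(
        [
            [4.1, 0.43, 1.67, 0.67, 0.003],
            [0.43, 4.4, 2.12, -0.74, 0.0],
            [1.67, 2.12, 382.0, 13.2, 0.059],
            [0.67, -0.74, 13.2, 111.8, 0.42],
            [0.003, 0.0, 0.059, 0.42, 0.003],
        ]
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-cohort generator (see docs/methods.md)."""

    daily_dose: float = STANDARD_DAILY_DOSE
    sigma_add: float = SIGMA_ADD
    sigma_prop: float = SIGMA_PROP
    activity_mean: float = 18.0
    activity_sd: float = 5.0
    activity_range: tuple[float, float] = (7.0, 30.0)
    #: CV of the multiplicative lognormal jitter between the deterministic
    #: activity->k_cm link and a patient's realized conversion rate.
    kcm_jitter_cv: float = 0.2
    e_max: float = E_MAX
    k_cm_max: float = K_CM_MAX


@dataclass(frozen=True)
class SolverConfig:
    """Integration accuracy knobs."""

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    fast_step: float = FAST_STEP
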