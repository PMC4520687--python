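import numpy as np
import pytest

from thiodose import config
from thiodose.inference import default_prior, sample_posterior_mcmc
from thiodose.pkmodel import DoseSchedule, PKParams
from thiodose.synthetic_data import generate_dataset
from thiodose.workflow import run_offline


@pytest.fixture(scope="session")
def mean_params() -> PKParams:
    """Population-mean kinetics."""
    return PKParams(4.2, 3.8, 39.4, 15.11, 0.08)


@pytest.fixture(scope="session")
def daily_doses() -> DoseSchedule:
    return DoseSchedule.daily(config.STANDARD_DAILY_DOSE, 75)


@pytest.fixture(scope="session")
def prior():
    return default_prior()


@pytest.fixture(scope="session")
def d1_cohort():
    """A reproducible D1-style cohort with its generating truths."""
    return generate_dataset("D1", seed=3)


@pytest.fixture(scope="session")
def offline_small(d1_cohort):
    """Offline artifacts from a 10-patient sub-cohort (shared across tests)."""
    series, _ = d1_cohort
    return run_offline(series[:10], seed=5, n_draws=2000, gsa_n_base=256, mcmc_chains=2)


def rk4_reference(theta, nu_cm, x0, dose_times, dose_amounts, infusion, out_times, h):
    """Plain-numpy fixed-step RK4 oracle, independent of the package kernels."""

    def rhs(x):
        k_ab, k_el, k_cm, K, k_me = theta
        sat = x[1] / (K + x[1])
        return np.array(
            [
                -k_ab * x[0] + infusion,
                k_ab * x[0] - k_el * x[1] - k_cm * sat,
                nu_cm * k_cm * sat - k_me * x[2],
            ]
        )

    x = np.array(x0, dtype=float)
    t = 0.0
    i_dose = 0
    out = np.empty((len(out_times), 3))

    def advance(t0, t1):
        nonlocal x
        if t1 <= t0:
            return
        n = int(np.ceil((t1 - t0) / h))
        dt = (t1 - t0) / n
        for _ in range(n):
            k1 = rhs(x)
            k2 = rhs(x + 0.5 * dt * k1)
            k3 = rhs(x + 0.5 * dt * k2)
            k4 = rhs(x + dt * k3)
            x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    for i, tt in enumerate(out_times):
        while i_dose < len(dose_times) and dose_times[i_dose] <= tt:
            advance(t, dose_times[i_dose])
            t = dose_times[i_dose]
            x[0] += dose_amounts[i_dose]
            i_dose += 1
        advance(t, tt)
        t = tt
        out[i] = x
    return out
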