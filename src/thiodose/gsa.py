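"""Sobol total-sensitivity analysis and sensitivity-based model reduction.

The question answered here: which kinetic parameters must be estimated per
patient, and which can safely be fixed at the population mean?  The total
Sobol index S_T of a parameter bounds (probabilistically) the normalized
output error incurred by fixing it: for any eps in (0, 1],

    P[ delta < (1 + 1/eps) * S_T ] >= 1 - eps

so with eps = 0.05 the multiplier is 21.  Indices are accumulated over a set
of representative times spanning the treatment period; parameters whose
cumulative bound falls below a small fraction of the largest are fixed.

Total indices are estimated with the Jansen estimator on a scrambled-Sobol
quasi-random base sample.  Inputs are sampled from the *independent*
marginals of the supplied prior (Sobol indices are defined for independent
inputs; the dependence structure of the population prior is deliberately
dropped here and noted in the report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import config
from .inference import PopulationPrior
from .pkmodel import DoseSchedule, simulate_xm_batch

__all__ = [
    "SensitivityReport",
    "sobol_indices",
    "total_indices",
    "xm_total_indices",
    "fixing_error_bound",
    "partition_parameters",
    "sensitivity_report",
    "empirical_bound_frequency",
]


def sobol_indices(
    model: Callable[[np.ndarray], np.ndarray],
    samplers: Sequence[Callable[[np.ndarray], np.ndarray]],
    n_base: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order and total Sobol indices by the Jansen estimators.

    ``model`` maps an (n, d) input matrix to (n, m) outputs; ``samplers``
    holds one inverse-CDF per input dimension (u in [0,1) -> value).
    Returns (S1, ST), each of shape (m, d).  Uses a scrambled Sobol
    sequence for the two base matrices; seed-reproducible.
    """
    d = len(samplers)
    if n_base < 64:
        raise ValueError("n_base must be at least 64")
    eng = qmc.Sobol(2 * d, scramble=True, rng=np.random.default_rng(seed))
    with warnings.catch_warnings():
        # non-power-of-two sample sizes are fine for this estimator
        warnings.simplefilter("ignore", UserWarning)
        u = eng.random(n_base)
    A = np.column_stack([samplers[j](u[:, j]) for j in range(d)])
    B = np.column_stack([samplers[j](u[:, d + j]) for j in range(d)])
    fA = np.atleast_2d(model(A))
    fB = np.atleast_2d(model(B))
    var = np.var(np.vstack([fA, fB]), axis=0, ddof=1)
    s1 = np.empty((fA.shape[1], d))
    st = np.empty((fA.shape[1], d))
    for j in range(d):
        ABj = A.copy()
        ABj[:, j] = B[:, j]
        fABj = model(ABj)
        st[:, j] = 0.5 * np.mean((fA - fABj) ** 2, axis=0) / var
        s1[:, j] = (var - 0.5 * np.mean((fB - fABj) ** 2, axis=0)) / var
    if np.any(st < -0.05):
        warnings.warn("total index below -0.05: increase n_base", stacklevel=2)
    return s1, st


def total_indices(
    model: Callable[[np.ndarray], np.ndarray],
    samplers: Sequence[Callable[[np.ndarray], np.ndarray]],
    n_base: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Total-order Sobol indices (see :func:`sobol_indices`)."""
    return sobol_indices(model, samplers, n_base, seed)[1]


def _marginal_samplers(prior: PopulationPrior, names: Sequence[str]):
    """Empirical inverse-CDFs of the prior's independent marginals."""
    samples = prior.as_samples()
    out = []
    for name in names:
        x = samples.param(name)
        order = np.argsort(x)
        xs = x[order]
        cw = np.cumsum(samples.weights[order])
        cw = cw / cw[-1]
        out.append(lambda u, xs=xs, cw=cw: np.interp(u, cw, xs))
    return out


def xm_total_indices(
    prior: PopulationPrior,
    doses: DoseSchedule,
    times: Sequence[float] = config.GSA_TIMES,
    n_base: int = 1000,
    seed: int = 0,
    nu_cm: float = 1.0,
) -> pd.DataFrame:
    """Total indices of the 6-TGN output at each evaluation time.

    Rows are times, columns the five kinetic parameters.  Only the kinetic
    parameters enter: the error-model parameters do not affect the
    noise-free output.
    """
    names = config.PK_PARAM_NAMES
    samplers = _marginal_samplers(prior, names)
    times = np.asarray(times, dtype=float)

    def model(thetas: np.ndarray) -> np.ndarray:
        return simulate_xm_batch(thetas, doses, times, nu_cm=nu_cm)

    st = total_indices(model, samplers, n_base=n_base, seed=seed)
    return pd.DataFrame(st, index=times, columns=list(names))


def fixing_error_bound(s_t_per_time: Sequence[float], eps: float = 0.05) -> float:
    """Cumulative probabilistic bound on the error of fixing one parameter.

    Sum over evaluation times of (1 + 1/eps) * S_T(t); holds with
    probability at least 1 - eps per time point.  With eps = 0.05 the
    per-time multiplier is 21.
    """
    if not 0 < eps <= 1:
        raise ValueError("eps must be in (0, 1]")
    s = np.asarray(s_t_per_time, dtype=float)
    if np.any(s < 0):
        raise ValueError("total indices must be non-negative")
    return float((1.0 + 1.0 / eps) * s.sum())


@dataclass
class SensitivityReport:
    """Per-parameter sensitivity summary and the estimation partition."""

    indices: pd.DataFrame  # times x parameters, total Sobol indices
    bounds: dict[str, float]  # cumulative fixing-error bound per parameter
    relative_pct: dict[str, float]  # bound as % of the maximum, in [0, 100]
    sensitive: tuple[str, ...]  # above-threshold parameters
    estimate: tuple[str, ...]  # sensitive minus correlation-pruned
    insensitive: dict[str, float]  # fixed parameters with nominal values
    threshold_pct: float
    eps: float
    notes: str = (
        "indices computed from independent marginals of the population prior; "
        "prior correlations are not propagated"
    )

    def to_json_dict(self) -> dict:
        return {
            "bounds": self.bounds,
            "relative_pct": self.relative_pct,
            "sensitive": list(self.sensitive),
            "estimate": list(self.estimate),
            "insensitive": self.insensitive,
            "threshold_pct": self.threshold_pct,
            "eps": self.eps,
            "notes": self.notes,
        }


def partition_parameters(
    bounds: dict[str, float],
    nominals: dict[str, float],
    corr: pd.DataFrame | None = None,
    threshold_pct: float = 2.0,
    corr_cut: float = 0.9,
) -> tuple[tuple[str, ...], tuple[str, ...], dict[str, float]]:
    """Split parameters into sensitive / estimated / fixed sets.

    A parameter is *sensitive* when its cumulative bound is at least
    ``threshold_pct`` percent of the largest bound.  Among sensitive pairs
    whose posterior correlation exceeds ``corr_cut`` in magnitude, only the
    larger-error member is retained for estimation (the other is fixed: a
    nearly collinear pair carries one effective degree of freedom).
    Returns (sensitive, estimate, fixed_with_nominals).
    """
    if not bounds:
        raise ValueError("empty bounds")
    vmax = max(bounds.values())
    if vmax <= 0:
        raise ValueError("degenerate model: all sensitivity bounds are zero")
    rel = {k: 100.0 * v / vmax for k, v in bounds.items()}
    sensitive = tuple(k for k in bounds if rel[k] >= threshold_pct)
    if not sensitive:
        raise ValueError("degenerate model: no sensitive parameter")
    estimate = list(sensitive)
    if corr is not None:
        for i, a in enumerate(sensitive):
            for b in sensitive[i + 1 :]:
                if a in estimate and b in estimate and abs(float(corr.loc[a, b])) > corr_cut:
                    estimate.remove(a if bounds[a] < bounds[b] else b)
    fixed = {k: float(nominals[k]) for k in bounds if k not in estimate}
    return sensitive, tuple(estimate), fixed


def sensitivity_report(
    prior: PopulationPrior,
    doses: DoseSchedule,
    times: Sequence[float] = config.GSA_TIMES,
    n_base: int = 1000,
    seed: int = 0,
    eps: float = 0.05,
    threshold_pct: float = 2.0,
    corr_cut: float = 0.9,
    nu_cm: float = 1.0,
) -> SensitivityReport:
    """Full GSA -> error-bound -> partition pipeline on the 6-TGN output."""
    idx = xm_total_indices(prior, doses, times, n_base, seed, nu_cm)
    bounds = {
        name: fixing_error_bound(np.clip(idx[name].to_numpy(), 0.0, None), eps)
        for name in idx.columns
    }
    vmax = max(bounds.values())
    rel = {k: 100.0 * v / vmax for k, v in bounds.items()}
    names = list(idx.columns)
    mean = prior.mvn_mean
    cov = prior.mvn_cov
    sd = np.sqrt(np.diag(cov))
    corr = pd.DataFrame(
        cov[: len(names), : len(names)]
        / np.outer(sd[: len(names)], sd[: len(names)]),
        index=names,
        columns=names,
    )
    nominals = {n: float(mean[prior.names.index(n)]) for n in names}
    sensitive, estimate, fixed = partition_parameters(
        bounds, nominals, corr, threshold_pct, corr_cut
    )
    return SensitivityReport(
        idx, bounds, rel, sensitive, estimate, fixed, threshold_pct, eps
    )


def empirical_bound_frequency(
    model: Callable[[np.ndarray], np.ndarray],
    samplers: Sequence[Callable[[np.ndarray], np.ndarray]],
    fix_index: int,
    nominal: float,
    s_total: float,
    n_draws: int = 2000,
    eps: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of prior draws whose fixing error stays below the bound.

    The fixing error of draw theta is the variance-normalized squared output
    discrepancy delta = (f(theta) - f(theta with component ``fix_index`` set
    to ``nominal``))^2 / Var[f]; the bound is (1 + 1/eps) * S_T.  For scalar
    output models only.
    """
    rng = np.random.default_rng(seed)
    u = rng.random((n_draws, len(samplers)))
    theta = np.column_stack([samplers[j](u[:, j]) for j in range(len(samplers))])
    f_full = np.asarray(model(theta), dtype=float).reshape(n_draws, -1)
    if f_full.shape[1] != 1:
        raise ValueError("calibration is defined for scalar outputs")
    fixed = theta.copy()
    fixed[:, fix_index] = nominal
    f_fixed = np.asarray(model(fixed), dtype=float).reshape(n_draws, -1)
    var = float(np.var(f_full, ddof=1))
    delta = (f_full - f_fixed) ** 2 / var
    bound = (1.0 + 1.0 / eps) * s_total
    return float(np.mean(delta < bound))
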