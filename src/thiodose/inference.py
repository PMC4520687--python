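"""Per-patient likelihood, MLE, Bayesian posteriors and pooled priors.

The observation model for a patient's sparse 6-TGN measurements is Gaussian
with a heteroscedastic standard deviation combining an additive assay floor
and a proportional component::

    y_j = xm(t_j; theta) + eps_j,   eps_j ~ N(0, (sigma_add + sigma_prop * xm_j)^2)

Posteriors over the joint vector (k_ab, k_el, k_cm, K, k_me, sigma_add,
sigma_prop) are obtained either by adaptive random-walk Metropolis-Hastings
on log-parameters or by a variational Gaussian approximation in log-space
(both target the same unnormalized posterior, prior x likelihood).  Patient
posteriors are pooled into a population prior — a mixture weighted by each
patient's data count — and restricted to TPMT-activity windows to form group
priors for incoming patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import binom

from . import config
from ._ode import rk4_states
from ._stats import ensure_pd, hpd_interval, split_rhat, weighted_mean_cov
from .exceptions import EmptyGroupError, LikelihoodError
from .pkmodel import DoseSchedule, PKParams, TPMTActivity

__all__ = [
    "ErrorParams",
    "MeasurementSeries",
    "PosteriorSamples",
    "PopulationPrior",
    "LogNormalPrior",
    "VBApprox",
    "Band",
    "LackOfFit",
    "default_prior",
    "log_likelihood",
    "fit_mle",
    "adaptive_metropolis",
    "sample_posterior_mcmc",
    "gaussian_elbo_fit",
    "fit_variational",
    "build_population_prior",
    "build_group_prior",
    "predictive_band",
    "lack_of_fit",
]

NAMES = config.ALL_PARAM_NAMES
_IDX = {n: i for i, n in enumerate(NAMES)}

#: default box constraints (natural scale) for optimization and MCMC support
DEFAULT_BOUNDS = {
    "k_ab": (0.1, 50.0),
    "k_el": (0.1, 50.0),
    "k_cm": (0.5, 500.0),
    "K": (0.5, 500.0),
    "k_me": (5e-3, 2.0),
    "sigma_add": (1e-2, 200.0),
    "sigma_prop": (1e-4, 1.0),
}


@dataclass(frozen=True)
class ErrorParams:
    """Measurement-error model parameters."""

    sigma_add: float  # additive SD, pmol/8e8 RBCs
    sigma_prop: float  # proportional SD, dimensionless

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("error SDs must be non-negative")
        if self.sigma_add == 0 and self.sigma_prop == 0:
            raise ValueError("at least one error component must be positive")


@dataclass(frozen=True)
class MeasurementSeries:
    """Sparse timed 6-TGN observations for one patient."""

    patient_id: str
    times: np.ndarray  # days, sorted
    y: np.ndarray  # observed 6-TGN, pmol/8e8 RBCs
    doses: DoseSchedule
    activity: TPMTActivity | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "y", y)
        if times.size == 0:
            raise ValueError("at least one observation is required")
        if times.size != y.size:
            raise ValueError("times and y must have equal length")
        if np.any(np.diff(times) < 0):
            raise ValueError("observation times must be sorted")
        if np.any(y < 0):
            raise ValueError("observed concentrations must be non-negative")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class PosteriorSamples:
    """Weighted joint draws over (k_ab, k_el, k_cm, K, k_me, sigma_add, sigma_prop)."""

    draws: np.ndarray  # (n, 7), natural scale
    weights: np.ndarray  # (n,), non-negative, sum 1
    provenance: dict = field(default_factory=dict)
    names: tuple[str, ...] = NAMES

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w / w.sum()
        if self.draws.shape[0] != self.weights.size:
            raise ValueError("draws and weights must align")
        if np.any(self.draws <= 0):
            raise ValueError("parameter draws must be positive")

    def param(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def mean(self) -> np.ndarray:
        return self.weights @ self.draws

    def cov(self) -> np.ndarray:
        return weighted_mean_cov(self.draws, self.weights)[1]

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov()))

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` rows with replacement according to the weights."""
        idx = rng.choice(self.draws.shape[0], size=n, p=self.weights)
        return self.draws[idx]

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval for one parameter (weighted quantiles)."""
        x = self.param(name)
        order = np.argsort(x)
        cw = np.cumsum(self.weights[order])
        lo = x[order][np.searchsorted(cw, (1 - level) / 2)]
        hi = x[order][min(np.searchsorted(cw, 1 - (1 - level) / 2), x.size - 1)]
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.names))
        df["weight"] = self.weights
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None):
        w = df["weight"].to_numpy() if "weight" in df else np.ones(len(df))
        return cls(df[list(NAMES)].to_numpy(), w, provenance or {})


class LogNormalPrior:
    """Multivariate lognormal prior: Gaussian over log-parameters."""

    def __init__(self, names: Sequence[str], log_mu: np.ndarray, log_cov: np.ndarray):
        self.names = tuple(names)
        self.log_mu = np.asarray(log_mu, dtype=float)
        self.log_cov = ensure_pd(np.asarray(log_cov, dtype=float))
        self._chol = np.linalg.cholesky(self.log_cov)
        self._prec = np.linalg.inv(self.log_cov)
        sign, logdet = np.linalg.slogdet(self.log_cov)
        self._lognorm = -0.5 * (len(self.names) * np.log(2 * np.pi) + logdet)

    @classmethod
    def from_moments(cls, names, mean, cov) -> "LogNormalPrior":
        """Moment-match natural-scale mean/covariance to a lognormal."""
        m = np.asarray(mean, dtype=float)
        c = np.asarray(cov, dtype=float)
        log_cov = np.log1p(c / np.outer(m, m))
        log_mu = np.log(m) - 0.5 * np.diag(log_cov)
        return cls(names, log_mu, log_cov)

    @classmethod
    def from_draws(cls, names, draws, weights=None) -> "LogNormalPrior":
        """Gaussian fit in log-space to (weighted) positive draws."""
        mu, cov = weighted_mean_cov(np.log(draws), weights)
        return cls(names, mu, cov)

    def logpdf_log(self, x_log: np.ndarray) -> float:
        d = x_log - self.log_mu
        return float(self._lognorm - 0.5 * d @ self._prec @ d)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, len(self.names)))
        return np.exp(self.log_mu + z @ self._chol.T)

    def mean_natural(self) -> np.ndarray:
        return np.exp(self.log_mu + 0.5 * np.diag(self.log_cov))

    def marginal(self, names: Sequence[str]) -> "LogNormalPrior":
        idx = [self.names.index(n) for n in names]
        return LogNormalPrior(
            names, self.log_mu[idx], self.log_cov[np.ix_(idx, idx)]
        )


def default_prior(
    stats_mean: np.ndarray | None = None, stats_cov: np.ndarray | None = None
) -> LogNormalPrior:
    """Lognormal prior over all seven parameters.

    Kinetic block is moment-matched to the population statistics; the error
    parameters get independent weakly-informative lognormals centered on the
    generator defaults (median 10 pmol/8e8 RBCs additive, 5% proportional,
    log-SD 0.7 each).
    """
    m = config.population_mean() if stats_mean is None else np.asarray(stats_mean)
    c = config.population_cov() if stats_cov is None else np.asarray(stats_cov)
    pk = LogNormalPrior.from_moments(config.PK_PARAM_NAMES, m, c)
    log_mu = np.concatenate(
        [pk.log_mu, [np.log(config.SIGMA_ADD), np.log(config.SIGMA_PROP)]]
    )
    log_cov = np.zeros((7, 7))
    log_cov[:5, :5] = pk.log_cov
    log_cov[5, 5] = log_cov[6, 6] = 0.7**2
    return LogNormalPrior(NAMES, log_mu, log_cov)


@dataclass
class PopulationPrior:
    """Mixture of patient posteriors weighted by data quantity.

    ``draws``/``draw_weights`` realize the mixture exactly: component draws
    are concatenated and each inherits weight w_i / m_i, where w_i is the
    mixture weight of patient i and m_i its draw count.  ``mvn_mean`` /
    ``mvn_cov`` is the multivariate-normal approximation fitted to the pooled
    draws on the natural scale.
    """

    components: list[PosteriorSamples]
    weights: np.ndarray
    draws: np.ndarray
    draw_weights: np.ndarray
    mvn_mean: np.ndarray
    mvn_cov: np.ndarray
    names: tuple[str, ...] = NAMES

    def as_samples(self) -> PosteriorSamples:
        return PosteriorSamples(
            self.draws, self.draw_weights, {"kind": "population"}, self.names
        )

    def as_lognormal(self) -> LogNormalPrior:
        """Density used when this prior enters MCMC/VB (log-space Gaussian fit)."""
        return LogNormalPrior.from_draws(self.names, self.draws, self.draw_weights)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.as_samples().resample(n, rng)

    def marginal_sd(self, name: str) -> float:
        return float(np.sqrt(self.mvn_cov[self.names.index(name), self.names.index(name)]))


# ---------------------------------------------------------------------------
# likelihood


def _predictor(data: MeasurementSeries, nu_cm: float = 1.0, h: float = config.FAST_STEP):
    """Closure computing model-predicted 6-TGN at the observation times."""
    dt_ev, da_ev = data.doses.arrays()
    times = np.asarray(data.times, dtype=float)
    infusion = data.doses.infusion
    x0 = np.zeros(3)

    def predict(theta5: np.ndarray) -> np.ndarray:
        states = rk4_states(theta5, nu_cm, x0, dt_ev, da_ev, infusion, times, h)
        return states[:, 2]

    return predict


def _gauss_loglik(y: np.ndarray, yhat: np.ndarray, err: ErrorParams) -> float:
    if not np.all(np.isfinite(yhat)):
        raise LikelihoodError("non-finite model prediction")
    sigma = err.sigma_add + err.sigma_prop * np.clip(yhat, 0.0, None)
    if np.any(sigma <= 0):
        raise LikelihoodError("non-positive error SD")
    r = (y - yhat) / sigma
    return float(-0.5 * np.sum(r * r) - np.sum(np.log(sigma)) - 0.5 * y.size * np.log(2 * np.pi))


def log_likelihood(
    data: MeasurementSeries, params: PKParams, err: ErrorParams
) -> float:
    """Gaussian log-likelihood of the observed series under the model."""
    yhat = _predictor(data, params.nu_cm)(params.theta())
    return _gauss_loglik(data.y, yhat, err)


def _subset_logpost(
    data: MeasurementSeries,
    prior: LogNormalPrior | PopulationPrior,
    estimate: Sequence[str],
    fixed: dict[str, float] | None,
    nu_cm: float = 1.0,
) -> tuple[Callable[[np.ndarray], float], np.ndarray, np.ndarray]:
    """Log-posterior over log-parameters of ``estimate``; returns (f, x0, cov0)."""
    if isinstance(prior, PopulationPrior):
        prior = prior.as_lognormal()
    estimate = tuple(estimate)
    sub = prior.marginal(estimate) if tuple(prior.names) != estimate else prior
    fixed = dict(fixed or {})
    full = np.empty(7)
    for name, val in fixed.items():
        full[_IDX[name]] = val
    for name in NAMES:
        if name not in estimate and name not in fixed:
            raise ValueError(f"parameter {name} neither estimated nor fixed")
    est_idx = np.array([_IDX[n] for n in estimate])
    predict = _predictor(data, nu_cm)
    y = data.y
    lo = np.log([DEFAULT_BOUNDS[n][0] for n in estimate])
    hi = np.log([DEFAULT_BOUNDS[n][1] for n in estimate])

    def logpost(x_log: np.ndarray) -> float:
        if np.any(x_log < lo) or np.any(x_log > hi):
            return -np.inf
        full[est_idx] = np.exp(x_log)
        try:
            yhat = predict(full[:5])
            ll = _gauss_loglik(y, yhat, ErrorParams(full[5], full[6]))
        except LikelihoodError:
            return -np.inf
        return ll + sub.logpdf_log(x_log)

    return logpost, sub.log_mu.copy(), sub.log_cov.copy()


# ---------------------------------------------------------------------------
# maximum likelihood


def fit_mle(
    data: MeasurementSeries,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    nominals: dict[str, float] | None = None,
    nu_cm: float = 1.0,
) -> tuple[PKParams, ErrorParams]:
    """Box-constrained maximum-likelihood fit with multi-start.

    With fewer than four observations, the poorly identified parameters
    (k_ab, k_el, K) are fixed at ``nominals`` (population means by default)
    and only (k_cm, k_me, sigma_add, sigma_prop) are estimated; a warning is
    emitted.  At least two observations are required.
    """
    if data.n_obs < 2:
        raise ValueError("MLE needs at least 2 observations")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    nom = {
        **dict(zip(NAMES, np.r_[config.population_mean(), config.SIGMA_ADD, config.SIGMA_PROP])),
        **(nominals or {}),
    }
    if data.n_obs < 4:
        warnings.warn(
            "fewer observations than identifiable parameters; fixing "
            "k_ab, k_el, K at nominal values",
            stacklevel=2,
        )
        estimate = ("k_cm", "k_me", "sigma_add", "sigma_prop")
    else:
        estimate = NAMES
    fixed = {n: nom[n] for n in NAMES if n not in estimate}
    predict = _predictor(data, nu_cm)
    full = np.empty(7)
    for name, val in fixed.items():
        full[_IDX[name]] = val
    est_idx = np.array([_IDX[n] for n in estimate])

    def nll(x_log: np.ndarray) -> float:
        full[est_idx] = np.exp(x_log)
        try:
            return -_gauss_loglik(data.y, predict(full[:5]), ErrorParams(full[5], full[6]))
        except LikelihoodError:
            return 1e12

    rng = np.random.default_rng(seed)
    x_nom = np.log([nom[n] for n in estimate])
    starts = [x_nom] + [x_nom + 0.5 * rng.standard_normal(len(estimate)) for _ in range(n_starts - 1)]
    box = [tuple(np.log(bounds[n])) for n in estimate]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in box], [b[1] for b in box])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=box)
        if best is None or res.fun < best.fun:
            best = res
    full[est_idx] = np.exp(best.x)
    return (
        PKParams.from_theta(full[:5], nu_cm=nu_cm),
        ErrorParams(full[5], full[6]),
    )


# ---------------------------------------------------------------------------
# MCMC


def adaptive_metropolis(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    cov0: np.ndarray,
    n_draws: int = 4000,
    seed: int = 0,
    n_chains: int = 4,
    burn_frac: float = 0.5,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, dict]:
    """Adaptive random-walk Metropolis-Hastings.

    Proposal is Gaussian with covariance s^2 * C, where C is the running
    empirical covariance of the chain (Haario-style, frozen after burn-in)
    and s is tuned toward ``target_accept`` during burn-in.  Returns
    post-burn-in draws of shape (n_draws_total, dim) and diagnostics
    (acceptance rates, split-R-hat).
    """
    rng = np.random.default_rng(seed)
    dim = x0.size
    per_chain = int(np.ceil(n_draws / n_chains))
    n_iter = int(np.ceil(per_chain / (1.0 - burn_frac)))
    n_burn = n_iter - per_chain
    kept = np.empty((n_chains, per_chain, dim))
    accept_rates = []
    base_cov = ensure_pd(np.asarray(cov0, dtype=float))
    for c in range(n_chains):
        x = x0 + (0.0 if c == 0 else 0.1 * rng.standard_normal(dim) @ np.linalg.cholesky(base_cov).T)
        lp = logpost(x)
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            x = x0 + 0.1 * rng.standard_normal(dim) @ np.linalg.cholesky(base_cov).T
            lp = logpost(x)
            tries += 1
        if not np.isfinite(lp):
            raise LikelihoodError("could not find a finite starting point")
        log_s = np.log(2.38 / np.sqrt(dim))
        cov = base_cov.copy()
        chol = np.linalg.cholesky(cov)
        history = np.empty((n_iter, dim))
        n_acc = 0
        n_acc_total = 0
        for i in range(n_iter):
            prop = x + np.exp(log_s) * (chol @ rng.standard_normal(dim))
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_acc += 1
                n_acc_total += 1
            history[i] = x
            if i < n_burn:
                # scale adaptation toward the target acceptance rate
                if (i + 1) % 50 == 0:
                    rate = n_acc / 50.0
                    log_s += 0.5 * (rate - target_accept)
                    n_acc = 0
                # covariance adaptation from the chain history
                if (i + 1) % 200 == 0 and i > dim * 10:
                    emp = np.cov(history[: i + 1].T).reshape(dim, dim)
                    cov = ensure_pd(emp + 1e-8 * np.eye(dim))
                    chol = np.linalg.cholesky(cov)
            if i == n_burn - 1:
                n_acc = 0  # reset so the reported rate is post-burn-in
        kept[c] = history[n_burn:]
        accept_rates.append(n_acc_total / n_iter)
    rate = float(np.mean(accept_rates))
    if not 0.05 <= rate <= 0.8:
        warnings.warn(f"MCMC acceptance rate {rate:.3f} outside [0.05, 0.8]", stacklevel=2)
    diag = {
        "accept_rate": rate,
        "rhat": split_rhat(kept),
        "n_burn_per_chain": n_burn,
    }
    return kept.reshape(-1, dim)[:n_draws], diag


def sample_posterior_mcmc(
    data: MeasurementSeries,
    prior: LogNormalPrior | PopulationPrior,
    n_draws: int = 4000,
    seed: int = 0,
    estimate: Sequence[str] = NAMES,
    fixed: dict[str, float] | None = None,
    n_chains: int = 4,
    nu_cm: float = 1.0,
) -> PosteriorSamples:
    """Patient posterior by Metropolis-Hastings on log-parameters.

    ``estimate`` selects the sampled parameters; the remainder must be
    supplied in ``fixed`` (natural scale) and appear as constant columns of
    the returned draws.
    """
    logpost, x0, cov0 = _subset_logpost(data, prior, estimate, fixed, nu_cm)
    draws_log, diag = adaptive_metropolis(
        logpost, x0, cov0 * (2.38**2 / max(len(estimate), 1) / 4), n_draws, seed, n_chains
    )
    full = np.empty((draws_log.shape[0], 7))
    for name in NAMES:
        if name in estimate:
            full[:, _IDX[name]] = np.exp(draws_log[:, list(estimate).index(name)])
        else:
            full[:, _IDX[name]] = (fixed or {})[name]
    prov = {
        "kind": "patient",
        "patient_id": data.patient_id,
        "n_obs": data.n_obs,
        "activity": data.activity.e if data.activity else None,
        "estimate": tuple(estimate),
        "diagnostics": diag,
        "seed": seed,
    }
    return PosteriorSamples(full, np.ones(full.shape[0]), prov)


# ---------------------------------------------------------------------------
# variational approximation


@dataclass
class VBApprox:
    """Full-covariance Gaussian approximation over log-parameters."""

    names: tuple[str, ...]
    mean_log: np.ndarray
    cov_log: np.ndarray
    elbo: float
    converged: bool
    fixed: dict[str, float] = field(default_factory=dict)
    logpost: Callable[[np.ndarray], float] | None = None

    def _gauss_draws(self, n: int, rng: np.random.Generator) -> np.ndarray:
        chol = np.linalg.cholesky(ensure_pd(self.cov_log))
        return self.mean_log + rng.standard_normal((n, len(self.names))) @ chol.T

    def _full(self, sub: np.ndarray, weights: np.ndarray, prov: dict) -> PosteriorSamples:
        full = np.empty((sub.shape[0], 7))
        for name in NAMES:
            if name in self.names:
                full[:, _IDX[name]] = sub[:, self.names.index(name)]
            else:
                full[:, _IDX[name]] = self.fixed[name]
        return PosteriorSamples(full, weights, prov)

    def sample(self, n: int, rng: np.random.Generator) -> PosteriorSamples:
        """Unweighted draws from the Gaussian approximation itself."""
        sub = np.exp(self._gauss_draws(n, rng))
        return self._full(sub, np.ones(n), {"kind": "patient", "method": "vb"})

    def posterior_samples(self, n: int, rng: np.random.Generator) -> PosteriorSamples:
        """Importance-corrected posterior draws using q as the proposal.

        Self-normalized importance sampling with the fitted Gaussian removes
        the residual family bias of q (e.g. on skewed error-parameter
        marginals), at the cost of one posterior evaluation per draw.
        Requires the log-posterior retained from fitting.
        """
        if self.logpost is None:
            return self.sample(n, rng)
        x = self._gauss_draws(n, rng)
        d = x - self.mean_log
        prec = np.linalg.inv(ensure_pd(self.cov_log))
        logq = -0.5 * np.einsum("ij,jk,ik->i", d, prec, d)
        logp = np.array([self.logpost(row) for row in x])
        logw = logp - logq
        logw -= logw.max()
        w = np.exp(logw)
        return self._full(np.exp(x), w, {"kind": "patient", "method": "vb+is"})

    def natural_mean(self) -> np.ndarray:
        """Lognormal mean of each estimated parameter on the natural scale."""
        return np.exp(self.mean_log + 0.5 * np.diag(self.cov_log))


def gaussian_elbo_fit(
    logpost: Callable[[np.ndarray], float],
    init_mean: np.ndarray,
    init_cov: np.ndarray,
    seed: int = 0,
    n_mc: int = 16,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Maximize the evidence lower bound over a full-covariance Gaussian.

    ELBO(q) = E_q[log p~(x)] + entropy(q), estimated with a fixed antithetic
    standard-normal base sample (common random numbers make the objective
    deterministic and smooth in the variational parameters).  Returns
    (mean, cov, elbo, converged).
    """
    dim = init_mean.size
    rng = np.random.default_rng(seed)
    half = max(dim + 1, n_mc // 2)
    z_half = rng.standard_normal((half, dim))
    z = np.vstack([z_half, -z_half])
    # whiten the base sample: exact zero mean and identity covariance, so the
    # fixed-sample ELBO is exact for any quadratic log-posterior (no
    # overfitting of the variational covariance to sampling noise)
    C = z.T @ z / z.shape[0]
    z = z @ np.linalg.inv(np.linalg.cholesky(C)).T
    tril = np.tril_indices(dim, -1)
    L0 = np.linalg.cholesky(ensure_pd(init_cov))

    def unpack(phi):
        m = phi[:dim]
        L = np.zeros((dim, dim))
        L[np.diag_indices(dim)] = np.exp(phi[dim : 2 * dim])
        L[tril] = phi[2 * dim :]
        return m, L

    const = 0.5 * dim * (1.0 + np.log(2 * np.pi))
    fd = 1e-4  # step for per-point log-posterior gradients (log-scale params)
    eye = np.eye(dim)

    def neg_elbo_grad(phi):
        m, L = unpack(phi)
        pts = m + z @ L.T
        n = pts.shape[0]
        tot = 0.0
        gsum_m = np.zeros(dim)
        gz = np.zeros((dim, dim))  # sum_k g_k z_k^T
        for k in range(n):
            p = pts[k]
            lp = logpost(p)
            if not np.isfinite(lp):
                return 1e10, np.zeros(phi.size)
            g = np.empty(dim)
            for i in range(dim):
                g[i] = (logpost(p + fd * eye[i]) - logpost(p - fd * eye[i])) / (2 * fd)
            tot += lp
            gsum_m += g
            gz += np.outer(g, z[k])
        elbo = tot / n + const + np.sum(phi[dim : 2 * dim])
        grad = np.empty(phi.size)
        grad[:dim] = -gsum_m / n
        diag = np.diag_indices(dim)
        grad[dim : 2 * dim] = -(gz[diag] / n) * L[diag] - 1.0
        grad[2 * dim :] = -(gz / n)[tril]
        return -elbo, grad

    phi0 = np.concatenate([init_mean, np.log(np.diag(L0)), L0[tril]])
    res = minimize(
        neg_elbo_grad, phi0, method="L-BFGS-B", jac=True,
        options={"maxiter": max_iter},
    )
    m, L = unpack(res.x)
    return m, L @ L.T, -res.fun, bool(res.success)


def fit_variational(
    data: MeasurementSeries,
    prior: LogNormalPrior | PopulationPrior,
    seed: int = 0,
    estimate: Sequence[str] = NAMES,
    fixed: dict[str, float] | None = None,
    n_mc: int = 16,
    max_iter: int = 150,
    nu_cm: float = 1.0,
) -> VBApprox:
    """Variational Gaussian posterior in log-space.

    Initialized at the Laplace approximation (posterior mode plus inverse
    finite-difference Hessian), then refined by direct maximization of the
    Monte-Carlo evidence lower bound with fixed base draws.  The returned
    moments are directly comparable with :func:`sample_posterior_mcmc` on the
    same problem.
    """
    logpost, x0, cov0 = _subset_logpost(data, prior, estimate, fixed, nu_cm)
    dim = x0.size

    res = minimize(lambda x: -logpost(x), x0, method="Nelder-Mead",
                   options={"maxiter": 400 * dim, "fatol": 1e-8, "xatol": 1e-6})
    res2 = minimize(lambda x: -logpost(x), res.x, method="L-BFGS-B")
    x_map = res2.x if res2.fun <= res.fun else res.x

    # finite-difference Hessian of -logpost at the mode
    eps = 1e-3
    H = np.empty((dim, dim))
    f0 = -logpost(x_map)
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim)
            ej = np.zeros(dim)
            ei[i] = eps
            ej[j] = eps
            if i == j:
                H[i, i] = (-logpost(x_map + ei) - 2 * f0 - logpost(x_map - ei)) / eps**2
            else:
                fpp = -logpost(x_map + ei + ej)
                fpm = -logpost(x_map + ei - ej)
                fmp = -logpost(x_map - ei + ej)
                fmm = -logpost(x_map - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    cov_lap = ensure_pd(np.linalg.inv(ensure_pd(H, 1e-6)), 1e-8)

    m, cov, elbo, ok = gaussian_elbo_fit(logpost, x_map, cov_lap, seed, n_mc, max_iter)
    if not ok:
        warnings.warn("variational optimization did not converge; returning best iterate",
                      stacklevel=2)
    fixed = dict(fixed or {})
    return VBApprox(tuple(estimate), m, cov, elbo, ok, fixed, logpost)


# ---------------------------------------------------------------------------
# pooled priors


def build_population_prior(
    posteriors: Sequence[PosteriorSamples],
    n_points: Sequence[int],
    draws_per_point: int = 10000,
) -> PopulationPrior:
    """Pool patient posteriors into the population mixture prior.

    Mixture weights are proportional to each patient's data count (patient i
    contributes ``draws_per_point * n_i`` of the conceptual pooled sample;
    realized here by per-draw weighting, which has the same distribution with
    deterministic moments).  A multivariate normal is fitted to the pooled
    draws as the smooth reporting approximation.
    """
    if len(posteriors) == 0:
        raise ValueError("at least one posterior is required")
    n_points = np.asarray(n_points, dtype=float)
    if len(posteriors) != n_points.size or np.any(n_points <= 0):
        raise ValueError("n_points must be positive, one per posterior")
    w = n_points / n_points.sum()
    pooled = []
    pooled_w = []
    for wi, post in zip(w, posteriors):
        pooled.append(post.draws)
        pooled_w.append(wi * post.weights)
    draws = np.vstack(pooled)
    dw = np.concatenate(pooled_w)
    dw = dw / dw.sum()
    mean, cov = weighted_mean_cov(draws, dw)
    return PopulationPrior(list(posteriors), w, draws, dw, mean, ensure_pd(cov))


def build_group_prior(
    posteriors: Sequence[PosteriorSamples],
    activities: Sequence[float],
    n_points: Sequence[int],
    window: tuple[float, float],
) -> PosteriorSamples:
    """Mixture restricted to patients whose TPMT activity lies in (lo, hi]."""
    lo, hi = window
    members = [
        i for i, a in enumerate(activities) if a is not None and lo < a <= hi
    ]
    if not members:
        raise EmptyGroupError(f"no patient with activity in ({lo}, {hi}]")
    sel_posts = [posteriors[i] for i in members]
    sel_n = [n_points[i] for i in members]
    pop = build_population_prior(sel_posts, sel_n, draws_per_point=1)
    return PosteriorSamples(
        pop.draws,
        pop.draw_weights,
        {"kind": "group", "window": (lo, hi), "n_members": len(members)},
    )


# ---------------------------------------------------------------------------
# predictive checking


@dataclass(frozen=True)
class Band:
    """Per-time highest-density interval of the predictive distribution."""

    times: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float

    def width(self) -> np.ndarray:
        return self.hi - self.lo

    def mean_width(self) -> float:
        return float(np.mean(self.width()))

    def contains(self, times: np.ndarray, y: np.ndarray) -> np.ndarray:
        lo = np.interp(times, self.times, self.lo)
        hi = np.interp(times, self.times, self.hi)
        return (y >= lo) & (y <= hi)


def predictive_band(
    post: PosteriorSamples,
    doses: DoseSchedule,
    times: Sequence[float],
    level: float = 0.95,
    n_draws: int = 500,
    seed: int = 0,
    include_noise: bool = True,
    nu_cm: float = 1.0,
) -> Band:
    """Posterior-predictive HPD band for the 6-TGN trajectory.

    Simulates each (resampled) parameter draw, optionally adds one
    measurement-noise realization per draw and time, and returns the
    shortest-interval HPD of the pointwise predictive sample.
    """
    if post.draws.shape[0] < 100:
        warnings.warn("fewer than 100 posterior draws; band will be noisy", stacklevel=2)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    draws = post.resample(n_draws, rng)
    from .pkmodel import simulate_xm_batch  # local import to avoid cycle

    xm = simulate_xm_batch(draws[:, :5], doses, times, nu_cm=nu_cm)
    if include_noise:
        sigma = draws[:, 5:6] + draws[:, 6:7] * np.clip(xm, 0.0, None)
        xm = xm + sigma * rng.standard_normal(xm.shape)
    lo = np.empty(times.size)
    hi = np.empty(times.size)
    for j in range(times.size):
        lo[j], hi[j] = hpd_interval(xm[:, j], level)
    return Band(times, lo, hi, level)


@dataclass(frozen=True)
class LackOfFit:
    n_inside: int
    n_total: int
    confidence: float

    @property
    def adequate(self) -> bool:
        """Model deemed adequate when the lack-of-fit confidence is < 0.05."""
        return self.confidence < 0.05


def lack_of_fit(times: np.ndarray, y: np.ndarray, band: Band) -> LackOfFit:
    """Global lack-of-fit test from HPD-band membership counts.

    With miss rate alpha = 1 - level, the number of points outside the band
    is Binomial(n, alpha) under the model.  The reported confidence is the
    lower tail P[X <= n_outside]: a small value means no more misses than
    chance predicts (adequate fit); values near 1 indicate gross misfit.
    """
    inside = band.contains(np.asarray(times, float), np.asarray(y, float))
    n_total = int(inside.size)
    n_inside = int(inside.sum())
    alpha = 1.0 - band.level
    conf = float(binom.cdf(n_total - n_inside, n_total, alpha))
    return LackOfFit(n_inside, n_total, conf)
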