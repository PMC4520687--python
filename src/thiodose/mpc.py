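"""Robust receding-horizon optimization of daily 6-MP doses.

The controller holds the 6-TGN concentration at a target inside the
therapeutic window by minimizing the expected squared setpoint deviation
over a frozen set of posterior parameter draws (sample-average
approximation).  Doses are constant within clinic-visit blocks (daily oral
boluses), bounded above and below, and rate-limited between consecutive
blocks.  In closed loop only the leading block is administered; after each
new 6-TGN measurement the posterior is updated and the remaining horizon is
re-optimized — the in-silico counterpart of a biweekly clinic visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from . import config
from .exceptions import InfeasibleControlError
from .inference import (
    ErrorParams,
    LogNormalPrior,
    MeasurementSeries,
    PosteriorSamples,
    sample_posterior_mcmc,
)
from .pkmodel import DoseSchedule, PKParams, simulate_fast, simulate_xm_batch

__all__ = ["ControlConfig", "ControlPlan", "tracking_cost", "optimize_dose", "closed_loop"]


@dataclass(frozen=True)
class ControlConfig:
    """Controller settings (units: days, pmol, pmol/8e8 RBCs)."""

    setpoint: float = config.TARGET_CONCENTRATION
    window: tuple[float, float] = config.THERAPEUTIC_WINDOW
    horizon: int = 75  # prediction horizon, days
    block: int = 15  # clinic-visit block length, days
    u_min: float = 0.0  # daily dose lower bound, pmol/day
    u_max: float = 2.5 * config.STANDARD_DAILY_DOSE
    du_min: float = -0.5 * config.STANDARD_DAILY_DOSE  # slew per block
    du_max: float = 0.5 * config.STANDARD_DAILY_DOSE
    n_samples: int = 50  # posterior draws in the sample-average cost
    nu_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.u_min > self.u_max:
            raise ValueError("u_min must not exceed u_max")
        if not self.window[0] < self.setpoint < self.window[1]:
            raise ValueError("setpoint must lie inside the therapeutic window")
        if self.horizon % self.block != 0:
            raise ValueError("block length must divide the horizon")

    @property
    def n_blocks(self) -> int:
        return self.horizon // self.block


@dataclass
class ControlPlan:
    """Optimized block doses with the predicted concentration band."""

    U: np.ndarray  # per-block daily dose, pmol/day
    cost: float
    pred_times: np.ndarray
    pred_mean: np.ndarray
    pred_lo: np.ndarray
    pred_hi: np.ndarray
    cfg: ControlConfig

    def daily_doses(self) -> np.ndarray:
        return np.repeat(self.U, self.cfg.block)


def _expand(U: np.ndarray, block: int) -> np.ndarray:
    return np.repeat(np.asarray(U, dtype=float), block)


def _daily_schedule(daily: np.ndarray, start: float = 0.0) -> DoseSchedule:
    return DoseSchedule(tuple((start + i, float(a)) for i, a in enumerate(daily)))


def _cost_of_daily(
    daily: np.ndarray,
    draws: np.ndarray,
    weights: np.ndarray,
    cfg: ControlConfig,
    x0: np.ndarray,
) -> float:
    times = np.arange(1.0, daily.size + 1.0)
    doses = _daily_schedule(daily)
    xm = simulate_xm_batch(draws[:, :5], doses, times, nu_cm=cfg.nu_cm, init=x0)
    dev = cfg.setpoint - xm
    return float(weights @ np.sum(dev * dev, axis=1))


def tracking_cost(
    U: Sequence[float],
    posterior: PosteriorSamples,
    cfg: ControlConfig,
    x0: Sequence[float] = (0.0, 0.0, 0.0),
) -> float:
    """Expected squared setpoint deviation at daily resolution.

    The expectation runs over the posterior draws with their weights; with a
    single draw this reduces to the deterministic sum of squared errors of
    that virtual patient.
    """
    U = np.asarray(U, dtype=float)
    if U.size != cfg.n_blocks:
        raise ValueError(f"expected {cfg.n_blocks} block doses, got {U.size}")
    return _cost_of_daily(
        _expand(U, cfg.block), posterior.draws, posterior.weights, cfg,
        np.asarray(x0, dtype=float),
    )


def _slew_constraints(cfg: ControlConfig, u_prev: float | None):
    cons = []
    n = cfg.n_blocks

    def du(U, k):
        return U[k] - (u_prev if k == 0 else U[k - 1])

    for k in range(n):
        if k == 0 and u_prev is None:
            continue
        cons.append({"type": "ineq", "fun": lambda U, k=k: du(U, k) - cfg.du_min})
        cons.append({"type": "ineq", "fun": lambda U, k=k: cfg.du_max - du(U, k)})
    return cons


def _project_feasible(U: np.ndarray, cfg: ControlConfig, u_prev: float | None) -> np.ndarray:
    """Forward-clip a plan so box and slew constraints hold exactly."""
    out = np.asarray(U, dtype=float).copy()
    prev = u_prev
    for k in range(out.size):
        lo, hi = cfg.u_min, cfg.u_max
        if prev is not None:
            lo = max(lo, prev + cfg.du_min)
            hi = min(hi, prev + cfg.du_max)
        if lo > hi:
            raise InfeasibleControlError("slew bounds incompatible with dose box")
        out[k] = min(max(out[k], lo), hi)
        prev = out[k]
    return out


def _feasible_start(cfg: ControlConfig, u_prev: float | None, target: float) -> np.ndarray:
    """Constant-dose start clipped into the box and reachable from u_prev."""
    n = cfg.n_blocks
    U = np.full(n, float(np.clip(target, cfg.u_min, cfg.u_max)))
    if u_prev is not None:
        for k in range(n):
            prev = u_prev if k == 0 else U[k - 1]
            U[k] = float(np.clip(U[k], prev + cfg.du_min, prev + cfg.du_max))
            U[k] = float(np.clip(U[k], cfg.u_min, cfg.u_max))
    return U


def optimize_dose(
    posterior: PosteriorSamples,
    cfg: ControlConfig,
    u_prev: float | None = None,
    seed: int = 0,
    x0: Sequence[float] = (0.0, 0.0, 0.0),
) -> ControlPlan:
    """Minimize the sample-average tracking cost over block doses.

    The posterior is frozen into ``cfg.n_samples`` draws (sample-average
    approximation); optimization is SLSQP with box and slew constraints from
    three starts.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_take = min(cfg.n_samples, posterior.draws.shape[0])
    if posterior.draws.shape[0] <= cfg.n_samples and np.allclose(
        posterior.weights, posterior.weights[0]
    ):
        draws = posterior.draws
    else:
        draws = posterior.resample(cfg.n_samples, rng)
    weights = np.full(draws.shape[0], 1.0 / draws.shape[0])
    x0 = np.asarray(x0, dtype=float)
    cons = _slew_constraints(cfg, u_prev)
    bounds = [(cfg.u_min, cfg.u_max)] * cfg.n_blocks

    if u_prev is not None:
        reach = u_prev + cfg.du_max * np.arange(1, cfg.n_blocks + 1)
        if np.all(reach.max() < cfg.u_min) or u_prev + cfg.du_min * 1 > cfg.u_max:
            raise InfeasibleControlError("slew bounds cannot reach the dose box")

    # steady-state-informed constant dose for the mean draw
    mean_p = PKParams.from_theta(np.maximum(draws[:, :5].mean(axis=0), 1e-9), nu_cm=cfg.nu_cm)
    u_ss = _target_infusion(mean_p, cfg.setpoint)
    starts = [
        _feasible_start(cfg, u_prev, u_ss),
        _feasible_start(cfg, u_prev, 0.5 * (cfg.u_min + cfg.u_max)),
        _feasible_start(cfg, u_prev, cfg.u_max),
    ]

    def cost(U):
        return _cost_of_daily(_expand(U, cfg.block), draws, weights, cfg, x0)

    best = None
    for s in starts:
        res = minimize(
            cost, s, method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 80, "ftol": 1e-6},
        )
        u_feas = _project_feasible(res.x, cfg, u_prev)
        val = cost(u_feas)
        if best is None or val < best[1]:
            best = (u_feas, val)
    U, J = best
    # constant fallback in case SLSQP wandered
    for s in starts:
        val = cost(s)
        if val < J:
            U, J = s, val
    daily = _expand(U, cfg.block)
    times = np.arange(1.0, cfg.horizon + 1.0)
    xm = simulate_xm_batch(draws[:, :5], _daily_schedule(daily), times, nu_cm=cfg.nu_cm, init=x0)
    return ControlPlan(
        U=U,
        cost=J,
        pred_times=times,
        pred_mean=xm.mean(axis=0),
        pred_lo=np.quantile(xm, 0.025, axis=0),
        pred_hi=np.quantile(xm, 0.975, axis=0),
        cfg=cfg,
    )


def _target_infusion(params: PKParams, target: float) -> float:
    """Constant daily input that sustains ``target`` 6-TGN at steady state."""
    rate_needed = target * params.k_me / params.nu_cm
    if rate_needed >= params.k_cm:
        return np.inf  # saturated: target unreachable, caller clips to u_max
    x_c = params.K * rate_needed / (params.k_cm - rate_needed)
    return params.k_el * x_c + rate_needed


@dataclass
class VisitRecord:
    day: float
    measurement: float
    posterior: PosteriorSamples
    plan: ControlPlan


@dataclass
class ClosedLoopHistory:
    """Everything the receding-horizon loop produced."""

    daily_doses: np.ndarray  # applied dose per day over the horizon
    times: np.ndarray  # daily grid
    true_xm: np.ndarray  # true-patient concentration on the daily grid
    visits: list[VisitRecord]
    initial_plan: ControlPlan
    cfg: ControlConfig


def closed_loop(
    true_params: PKParams,
    true_err: ErrorParams,
    prior: PosteriorSamples,
    cfg: ControlConfig,
    measurement_days: Sequence[float],
    seed: int = 0,
    estimate: Sequence[str] = ("k_cm",),
    fixed: dict[str, float] | None = None,
    prior_density: LogNormalPrior | None = None,
    n_mcmc: int = 2000,
) -> ClosedLoopHistory:
    """Receding-horizon simulation against a virtual true patient.

    At each measurement day the true patient is simulated forward under the
    doses applied so far, a noisy 6-TGN measurement is taken, the posterior
    over ``estimate`` is refreshed by MCMC (remaining parameters fixed at
    ``fixed``, the population means by default), and the remaining blocks are
    re-optimized.  Measurement days must be multiples of the block length.
    """
    measurement_days = sorted(float(d) for d in measurement_days)
    if any(d % cfg.block != 0 or not 0 < d < cfg.horizon for d in measurement_days):
        raise ValueError("measurement days must be interior block boundaries")
    rng = np.random.default_rng(seed)
    if fixed is None:
        post_mean = prior.mean()
        fixed = {
            name: float(post_mean[list(prior.names).index(name)])
            for name in prior.names
            if name not in estimate
        }
    if prior_density is None:
        prior_density = LogNormalPrior.from_draws(prior.names, prior.draws, prior.weights)

    plan = optimize_dose(prior, cfg, seed=seed)
    daily = plan.daily_doses()
    visits: list[VisitRecord] = []
    current_post = prior
    meas_times: list[float] = []
    meas_values: list[float] = []
    for v, day in enumerate(measurement_days):
        di = int(day)
        truth = simulate_fast(
            true_params, _daily_schedule(daily[:di]), np.array([day])
        ).x_m[0]
        sigma = true_err.sigma_add + true_err.sigma_prop * max(truth, 0.0)
        y = max(truth + sigma * rng.standard_normal(), 0.0)
        meas_times.append(day)
        meas_values.append(y)
        series = MeasurementSeries(
            patient_id="closed-loop",
            times=np.array(meas_times),
            y=np.array(meas_values),
            doses=_daily_schedule(daily[:di]),
        )
        current_post = sample_posterior_mcmc(
            series,
            prior_density,
            n_draws=n_mcmc,
            seed=int(rng.integers(2**31 - 1)),
            estimate=tuple(estimate),
            fixed=fixed,
            n_chains=2,
        )
        # re-optimize the remaining blocks from the current (estimated) state
        remaining = cfg.horizon - di
        sub_cfg = ControlConfig(
            setpoint=cfg.setpoint, window=cfg.window, horizon=remaining,
            block=cfg.block, u_min=cfg.u_min, u_max=cfg.u_max,
            du_min=cfg.du_min, du_max=cfg.du_max, n_samples=cfg.n_samples,
            nu_cm=cfg.nu_cm,
        )
        mean_theta = current_post.mean()[:5]
        state = simulate_fast(
            PKParams.from_theta(mean_theta, nu_cm=cfg.nu_cm),
            _daily_schedule(daily[:di]),
            np.array([day]),
        )
        x_now = np.array([state.x_g[0], state.x_c[0], state.x_m[0]])
        sub_plan = optimize_dose(
            current_post, sub_cfg, u_prev=float(daily[di - 1]),
            seed=seed + 100 + v, x0=x_now,
        )
        daily = np.concatenate([daily[:di], sub_plan.daily_doses()])
        visits.append(VisitRecord(day, float(y), current_post, sub_plan))
    times = np.arange(1.0, cfg.horizon + 1.0)
    true_xm = simulate_fast(true_params, _daily_schedule(daily), times).x_m
    return ClosedLoopHistory(daily, times, true_xm, visits, plan, cfg)
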