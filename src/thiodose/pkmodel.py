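"""Three-state model of oral 6-mercaptopurine metabolism.

The model tracks 6-MP in the gut (``x_g``, pmol), 6-MP in plasma (``x_c``,
pmol) and the active metabolite 6-TGN in red blood cells (``x_m``,
pmol/8e8 RBCs)::

    dx_g/dt = -k_ab * x_g + d(t)
    dx_c/dt =  k_ab * x_g - k_el * x_c - k_cm * x_c / (K + x_c)
    dx_m/dt =  nu_cm * k_cm * x_c / (K + x_c) - k_me * x_m

Oral intake is fast relative to the daily dynamics, so dose events ``d(t)``
are treated as instantaneous additions to the gut compartment.  Conversion of
plasma 6-MP to 6-TGN follows Michaelis-Menten kinetics whose rate constant is
suppressed by the patient's TPMT activity: high TPMT activity diverts 6-MP
into methylated metabolites and away from 6-TGN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import config
from ._ode import rk4_states, rk4_xm_batch
from .exceptions import (
    IntegrationError,
    InfeasibleSteadyStateError,
    InvalidActivityError,
)

__all__ = [
    "PKParams",
    "TPMTActivity",
    "DoseSchedule",
    "Trajectory",
    "relative_activity",
    "effective_conversion_rate",
    "simulate",
    "simulate_fast",
    "simulate_xm_batch",
    "steady_state",
]


@dataclass(frozen=True)
class PKParams:
    """Kinetic parameters of one patient.

    ``k_cm`` is the *effective* conversion rate: when a parameter set is
    derived from a TPMT activity, the activity modulation has already been
    applied (see :func:`effective_conversion_rate`); it is never applied a
    second time during simulation or fitting.
    """

    k_ab: float  # absorption rate, 1/day
    k_el: float  # plasma elimination rate, 1/day
    k_cm: float  # 6-MP -> 6-TGN conversion rate, pmol/day
    K: float  # Michaelis-Menten constant, pmol
    k_me: float  # 6-TGN elimination rate, 1/day
    nu_cm: float = 1.0  # stoichiometric yield, (pmol/8e8 RBCs) per pmol

    def __post_init__(self) -> None:
        for name in ("k_ab", "k_el", "k_cm", "K", "k_me"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nu_cm < 0:
            raise ValueError("nu_cm must be non-negative")

    def theta(self) -> np.ndarray:
        """(k_ab, k_el, k_cm, K, k_me) as an array."""
        return np.array([self.k_ab, self.k_el, self.k_cm, self.K, self.k_me])

    @classmethod
    def from_theta(cls, theta: Sequence[float], nu_cm: float = 1.0) -> "PKParams":
        return cls(*[float(v) for v in theta], nu_cm=nu_cm)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PKParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class TPMTActivity:
    """Measured TPMT enzyme activity and the conversion-rate ceiling."""

    e: float  # measured activity, U/ml/hr
    e_max: float = config.E_MAX
    k_cm_max: float = config.K_CM_MAX

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise InvalidActivityError(f"e_max must be positive, got {self.e_max}")
        if not 0 <= self.e <= self.e_max:
            raise InvalidActivityError(
                f"activity {self.e} outside [0, {self.e_max}] U/ml/hr"
            )


@dataclass(frozen=True)
class DoseSchedule:
    """Timed oral 6-MP boluses plus an optional constant gut input.

    ``events`` is a sequence of ``(time_day, amount_pmol)`` pairs, sorted by
    time; ``infusion`` is a constant input rate in pmol/day.
    """

    events: tuple[tuple[float, float], ...] = ()
    infusion: float = 0.0

    def __post_init__(self) -> None:
        events = tuple((float(t), float(a)) for t, a in self.events)
        object.__setattr__(self, "events", events)
        times = [t for t, _ in events]
        if any(t < 0 for t in times):
            raise ValueError("dose event times must be non-negative")
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted by time")
        if any(a < 0 for _, a in events):
            raise ValueError("dose amounts must be non-negative")
        if self.infusion < 0:
            raise ValueError("infusion must be non-negative")

    @classmethod
    def daily(cls, amount: float, n_days: int, start: float = 0.0) -> "DoseSchedule":
        """One bolus of ``amount`` pmol per day for ``n_days`` days."""
        return cls(tuple((start + float(d), amount) for d in range(n_days)))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.events:
            return np.empty(0), np.empty(0)
        t, a = zip(*self.events)
        return np.asarray(t, dtype=float), np.asarray(a, dtype=float)

    def to_json(self) -> str:
        return json.dumps({"events": list(self.events), "infusion": self.infusion})

    @classmethod
    def from_json(cls, text: str) -> "DoseSchedule":
        d = json.loads(text)
        return cls(tuple((t, a) for t, a in d["events"]), d.get("infusion", 0.0))


@dataclass(frozen=True)
class Trajectory:
    """Simulated states at requested times."""

    times: np.ndarray
    x_g: np.ndarray
    x_c: np.ndarray
    x_m: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.x_g) == len(self.x_c) == len(self.x_m) == n):
            raise ValueError("state arrays must have the same length as times")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "x_g": self.x_g, "x_c": self.x_c, "x_m": self.x_m}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def relative_activity(act: TPMTActivity) -> float:
    """Activity as a fraction of its maximum, e_rel = e / e_max in [0, 1]."""
    return act.e / act.e_max


def effective_conversion_rate(act: TPMTActivity) -> float:
    """Conversion rate suppressed by TPMT activity.

    A fraction of 6-MP proportional to (1 - e_rel) follows the 6-TGN pathway,
    so k_cm = k_cm_max * (1 - e/e_max): monotone decreasing in activity, zero
    at full activity.
    """
    return act.k_cm_max * (1.0 - relative_activity(act))


def _rhs(t, x, th, nu_cm, infusion):
    k_ab, k_el, k_cm, K, k_me = th
    sat = x[1] / (K + x[1])
    return [
        -k_ab * x[0] + infusion,
        k_ab * x[0] - k_el * x[1] - k_cm * sat,
        nu_cm * k_cm * sat - k_me * x[2],
    ]


def simulate(
    params: PKParams,
    doses: DoseSchedule,
    times: Sequence[float],
    init: Sequence[float] = (0.0, 0.0, 0.0),
    solver: config.SolverConfig = config.SolverConfig(),
) -> Trajectory:
    """Reference simulation with adaptive error control.

    Integration is restarted at every bolus event (the dose is added to the
    gut state between segments), so discontinuities never degrade solver
    accuracy.  Output times coinciding with an event record the post-dose
    state.  Use :func:`simulate_fast` inside tight loops.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("output times must be sorted and non-negative")
    init = np.asarray(init, dtype=float)
    if init.shape != (3,) or np.any(init < 0):
        raise ValueError("init must be three non-negative state values")
    th = params.theta()
    dt_ev, da_ev = doses.arrays()

    out = np.empty((times.size, 3))
    x = init.copy()
    t = 0.0
    i_dose = 0

    def advance(t0: float, t1: float) -> None:
        nonlocal x
        if t1 <= t0:
            return
        sol = solve_ivp(
            _rhs,
            (t0, t1),
            x,
            args=(th, params.nu_cm, doses.infusion),
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0}, {t1}] at state {x.tolist()}: {sol.message}"
            )
        x = sol.y[:, -1]

    for i, t_target in enumerate(times):
        while i_dose < dt_ev.size and dt_ev[i_dose] <= t_target:
            advance(t, dt_ev[i_dose])
            t = dt_ev[i_dose]
            x = x.copy()
            x[0] += da_ev[i_dose]
            i_dose += 1
        advance(t, t_target)
        t = t_target
        out[i] = x
    return Trajectory(times, out[:, 0], out[:, 1], out[:, 2])


def simulate_fast(
    params: PKParams,
    doses: DoseSchedule,
    times: Sequence[float],
    init: Sequence[float] = (0.0, 0.0, 0.0),
    h: float = config.FAST_STEP,
) -> Trajectory:
    """Fixed-step (RK4) simulation; same event conventions as :func:`simulate`."""
    times = np.asarray(times, dtype=float)
    dt_ev, da_ev = doses.arrays()
    out = rk4_states(
        params.theta(),
        params.nu_cm,
        np.asarray(init, dtype=float),
        dt_ev,
        da_ev,
        doses.infusion,
        times,
        h,
    )
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite state in fixed-step integration")
    return Trajectory(times, out[:, 0], out[:, 1], out[:, 2])


def simulate_xm_batch(
    thetas: np.ndarray,
    doses: DoseSchedule,
    times: Sequence[float],
    nu_cm: float = 1.0,
    init: Sequence[float] = (0.0, 0.0, 0.0),
    h: float = config.FAST_STEP,
) -> np.ndarray:
    """6-TGN concentration at ``times`` for each parameter row (n, 5)."""
    dt_ev, da_ev = doses.arrays()
    return rk4_xm_batch(
        np.ascontiguousarray(thetas, dtype=float),
        nu_cm,
        np.asarray(init, dtype=float),
        dt_ev,
        da_ev,
        doses.infusion,
        np.asarray(times, dtype=float),
        h,
    )


def steady_state(params: PKParams, infusion: float) -> float:
    """Steady-state 6-TGN concentration under a constant gut input.

    Solves 0 = u - k_el*x_c - k_cm*x_c/(K + x_c) for the non-negative plasma
    level and returns nu_cm * k_cm * x_c / (K + x_c) / k_me.
    """
    if infusion < 0:
        raise ValueError("infusion must be non-negative")
    u = float(infusion)
    if u == 0.0:
        return 0.0
    # k_el * x^2 + (k_el*K + k_cm - u) * x - u*K = 0
    a, b, c = params.k_el, params.k_el * params.K + params.k_cm - u, -u * params.K
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise InfeasibleSteadyStateError("no real steady state")
    x_c = (-b + np.sqrt(disc)) / (2.0 * a)
    if x_c < 0:
        raise InfeasibleSteadyStateError("no non-negative steady state")
    return params.nu_cm * params.k_cm * x_c / (params.K + x_c) / params.k_me
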