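"""Compiled fixed-step integration kernels for the 6-MP metabolism model.

These kernels are the fast path used inside tight loops (MCMC, variational
optimization, Sobol sampling, MPC cost evaluation).  The reference path with
adaptive error control lives in :mod:`thiodose.pkmodel`.  All kernels use
classical RK4 with a fixed sub-step and restart the step grid at every bolus
event, so dose discontinuities never fall inside a step.

State layout: ``x = (x_g, x_c, x_m)`` — 6-MP in gut (pmol), 6-MP in plasma
(pmol), 6-TGN in RBCs (pmol/8e8 RBCs).  Parameter vector layout everywhere:
``theta = (k_ab, k_el, k_cm, K, k_me)``.
"""

import numpy as np
from numba import njit

__all__ = ["rk4_states", "rk4_xm_batch", "rk4_sensitivities"]


@njit(inline="always")
def _rhs(x, theta, nu_cm, infusion, out):
    k_ab, k_el, k_cm, K, k_me = theta[0], theta[1], theta[2], theta[3], theta[4]
    sat = x[1] / (K + x[1])
    out[0] = -k_ab * x[0] + infusion
    out[1] = k_ab * x[0] - k_el * x[1] - k_cm * sat
    out[2] = nu_cm * k_cm * sat - k_me * x[2]


@njit
def _rk4_segment(x, theta, nu_cm, infusion, t0, t1, h):
    """Advance state in place from t0 to t1 with step <= h (no events inside)."""
    span = t1 - t0
    if span <= 0.0:
        return
    n = int(np.ceil(span / h))
    dt = span / n
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    xt = np.empty(3)
    for _ in range(n):
        _rhs(x, theta, nu_cm, infusion, k1)
        for j in range(3):
            xt[j] = x[j] + 0.5 * dt * k1[j]
        _rhs(xt, theta, nu_cm, infusion, k2)
        for j in range(3):
            xt[j] = x[j] + 0.5 * dt * k2[j]
        _rhs(xt, theta, nu_cm, infusion, k3)
        for j in range(3):
            xt[j] = x[j] + dt * k3[j]
        _rhs(xt, theta, nu_cm, infusion, k4)
        for j in range(3):
            x[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])


@njit
def rk4_states(theta, nu_cm, x0, dose_times, dose_amounts, infusion, out_times, h):
    """Integrate the 3-state model, returning states at ``out_times``.

    Bolus amounts are added to x_g at their event times; when an output time
    coincides with an event, the recorded state is the post-dose (right)
    limit.  ``out_times`` and ``dose_times`` must be sorted ascending.
    """
    n_out = out_times.shape[0]
    out = np.empty((n_out, 3))
    x = x0.copy()
    t = 0.0
    i_dose = 0
    # events strictly before t=0 are not supported; clip
    for i in range(n_out):
        t_target = out_times[i]
        while i_dose < dose_times.shape[0] and dose_times[i_dose] <= t_target:
            _rk4_segment(x, theta, nu_cm, infusion, t, dose_times[i_dose], h)
            t = dose_times[i_dose]
            x[0] += dose_amounts[i_dose]
            i_dose += 1
        _rk4_segment(x, theta, nu_cm, infusion, t, t_target, h)
        t = t_target
        for j in range(3):
            out[i, j] = x[j]
    return out


@njit
def rk4_xm_batch(thetas, nu_cm, x0, dose_times, dose_amounts, infusion, out_times, h):
    """x_m at ``out_times`` for each parameter row in ``thetas`` (n, 5)."""
    n = thetas.shape[0]
    m = out_times.shape[0]
    out = np.empty((n, m))
    for i in range(n):
        states = rk4_states(
            thetas[i], nu_cm, x0, dose_times, dose_amounts, infusion, out_times, h
        )
        for j in range(m):
            out[i, j] = states[j, 2]
    return out


@njit(inline="always")
def _rhs_sens(z, theta, nu_cm, infusion, out):
    """RHS of the forward-sensitivity system: 3 states + 3x5 sensitivities.

    z layout: z[0:3] = states, z[3 + 3*p + k] = d x_k / d theta_p.
    Bolus inputs do not depend on theta, so sensitivities are continuous
    across dose events.
    """
    k_ab, k_el, k_cm, K, k_me = theta[0], theta[1], theta[2], theta[3], theta[4]
    xg, xc, xm = z[0], z[1], z[2]
    den = K + xc
    sat = xc / den
    dsat_dxc = K / (den * den)
    out[0] = -k_ab * xg + infusion
    out[1] = k_ab * xg - k_el * xc - k_cm * sat
    out[2] = nu_cm * k_cm * sat - k_me * xm
    # Jacobian wrt states
    # f1_xg = -k_ab
    # f2_xg = k_ab ; f2_xc = -k_el - k_cm*dsat
    # f3_xc = nu*k_cm*dsat ; f3_xm = -k_me
    for p in range(5):
        sg = z[3 + 3 * p + 0]
        sc = z[3 + 3 * p + 1]
        sm = z[3 + 3 * p + 2]
        fg = -k_ab * sg
        fc = k_ab * sg + (-k_el - k_cm * dsat_dxc) * sc
        fm = nu_cm * k_cm * dsat_dxc * sc - k_me * sm
        if p == 0:  # k_ab
            fg += -xg
            fc += xg
        elif p == 1:  # k_el
            fc += -xc
        elif p == 2:  # k_cm
            fc += -sat
            fm += nu_cm * sat
        elif p == 3:  # K
            fc += k_cm * xc / (den * den)
            fm += -nu_cm * k_cm * xc / (den * den)
        else:  # k_me
            fm += -xm
        out[3 + 3 * p + 0] = fg
        out[3 + 3 * p + 1] = fc
        out[3 + 3 * p + 2] = fm


@njit
def _rk4_segment_sens(z, theta, nu_cm, infusion, t0, t1, h):
    span = t1 - t0
    if span <= 0.0:
        return
    n = int(np.ceil(span / h))
    dt = span / n
    dim = z.shape[0]
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    zt = np.empty(dim)
    for _ in range(n):
        _rhs_sens(z, theta, nu_cm, infusion, k1)
        for j in range(dim):
            zt[j] = z[j] + 0.5 * dt * k1[j]
        _rhs_sens(zt, theta, nu_cm, infusion, k2)
        for j in range(dim):
            zt[j] = z[j] + 0.5 * dt * k2[j]
        _rhs_sens(zt, theta, nu_cm, infusion, k3)
        for j in range(dim):
            zt[j] = z[j] + dt * k3[j]
        _rhs_sens(zt, theta, nu_cm, infusion, k4)
        for j in range(dim):
            z[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])


@njit
def rk4_sensitivities(theta, nu_cm, x0, dose_times, dose_amounts, infusion, out_times, h):
    """States and d x / d theta at ``out_times``.

    Returns (states (m,3), sens (m,3,5)) with sens[j, k, p] = dx_k/dtheta_p
    at out_times[j].  Initial sensitivities are zero (x0 independent of theta).
    """
    m = out_times.shape[0]
    states = np.empty((m, 3))
    sens = np.empty((m, 3, 5))
    z = np.zeros(18)
    z[0] = x0[0]
    z[1] = x0[1]
    z[2] = x0[2]
    t = 0.0
    i_dose = 0
    for i in range(m):
        t_target = out_times[i]
        while i_dose < dose_times.shape[0] and dose_times[i_dose] <= t_target:
            _rk4_segment_sens(z, theta, nu_cm, infusion, t, dose_times[i_dose], h)
            t = dose_times[i_dose]
            z[0] += dose_amounts[i_dose]
            i_dose += 1
        _rk4_segment_sens(z, theta, nu_cm, infusion, t, t_target, h)
        t = t_target
        for k in range(3):
            states[i, k] = z[k]
        for p in range(5):
            for k in range(3):
                sens[i, k, p] = z[3 + 3 * p + k]
    return states, sens
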