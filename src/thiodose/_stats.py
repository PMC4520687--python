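"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["ensure_pd", "weighted_mean_cov", "split_rhat", "hpd_interval"]


def ensure_pd(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Symmetrize and clip eigenvalues so the matrix is positive definite."""
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w.min() >= floor:
        return cov
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


def weighted_mean_cov(x: np.ndarray, w: np.ndarray | None = None):
    """Weighted mean vector and covariance of rows of ``x``."""
    x = np.asarray(x, dtype=float)
    if w is None:
        w = np.full(x.shape[0], 1.0 / x.shape[0])
    else:
        w = np.asarray(w, dtype=float)
        w = w / w.sum()
    m = w @ x
    d = x - m
    cov = (d * w[:, None]).T @ d
    return m, cov


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per dimension for an array of shape (n_chains, n_draws, dim)."""
    c, n, d = chains.shape
    half = n // 2
    seq = chains[:, : 2 * half].reshape(2 * c, half, d)
    m = seq.mean(axis=1)  # (2c, d)
    s2 = seq.var(axis=1, ddof=1)
    w = s2.mean(axis=0)
    b = half * m.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return np.where(w > 0, rhat, 1.0)


def hpd_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted sample mass.

    With ``level == 1`` this is the full sample range.  Assumes a unimodal
    underlying density (the shortest-window estimator on sorted draws).
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = max(1, int(np.ceil(level * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])
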