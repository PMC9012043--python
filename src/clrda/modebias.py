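"""Compositional-bias estimation via the kernel-density mode.

Regression on CLR data estimates ``alpha_i - mean(alpha)``: every
coefficient is shifted by the same unknown constant.  When most taxa are
non-differential (``alpha_i = 0``), the scaled coefficients
``sqrt(n) * alpha_tilde_i`` pile up at ``-sqrt(n) * mean(alpha)``, so the
argmax of their kernel density estimate identifies the shift.  The
bias-corrected effects are ``alpha_hat_i = alpha_tilde_i - mode / sqrt(n)``.

The estimator relies on a mode at zero of the underlying signal
distribution, i.e. sparse differential signal; with few features the mode
is estimated poorly, hence the small-``m`` warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

SMALL_M_WARN = 50


@dataclass
class BiasEstimate:
    """Result of the mode-based bias correction.

    ``bias`` is the scalar added to every raw coefficient
    (``alpha_hat = alpha_tilde + bias``); on the scaled axis it equals
    ``-mode_value / sqrt(n)``.
    """

    bias: float
    mode_value: float
    h: float
    kernel: str
    grid_size: int


def _silverman(v: np.ndarray) -> float:
    m = v.size
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * m ** (-0.2)


def _density(x: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
    # unnormalized Gaussian KDE; the argmax is unaffected by the constant
    z = (np.atleast_1d(x)[:, None] - v[None, :]) / h
    with np.errstate(over="ignore"):
        return np.exp(-0.5 * np.minimum(z * z, 1e308)).sum(axis=1)


def kde_mode(
    values,
    kernel: str = "gaussian",
    h: float | None = None,
    grid_size: int = 1024,
    full_output: bool = False,
):
    """Argmax of the Gaussian kernel density estimate of ``values``.

    The density is evaluated on a ``grid_size``-point grid spanning
    ``[min - 3h, max + 3h]``; the winning cell (ties broken toward the
    candidate of smallest absolute value) is refined by bounded scalar
    optimization.  Deterministic for fixed inputs.  ``h=None`` uses
    Silverman's rule of thumb.
    """
    if kernel != "gaussian":
        raise ValueError(f"unsupported kernel {kernel!r}")
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values to estimate a mode")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if np.ptp(v) == 0:
        mode = float(v[0])
        return (mode, 0.0) if full_output else mode
    if h is None:
        h = _silverman(v)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_size)
    dens = _density(grid, v, h)
    top = dens.max()
    winners = np.flatnonzero(dens >= top * (1 - 1e-12))
    j = winners[np.argmin(np.abs(grid[winners]))]
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda x: -_density(np.array([x]), v, h)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10 * max(1.0, abs(hi - lo))},
    )
    mode = float(res.x) if -res.fun >= dens[j] else float(grid[j])
    return (mode, float(h)) if full_output else mode


def debias(fit, di, kernel: str = "gaussian", h: float | None = None):
    """Bias-correct the per-taxon coefficients.

    Returns ``(alpha_hat, BiasEstimate)`` where the same scalar correction
    ``-mode(sqrt(n) * alpha_tilde) / sqrt(n)`` is added to every taxon's raw
    coefficient.  Adding a constant to all raw coefficients leaves
    ``alpha_hat`` unchanged (shift invariance), which is the operational
    meaning of removing the compositional bias.
    """
    alpha_tilde = np.asarray(fit.alpha_tilde, dtype=float)
    m = alpha_tilde.size
    if m < 2:
        raise ValueError("need at least 2 taxa to estimate the bias")
    if m < SMALL_M_WARN:
        warnings.warn(
            f"only {m} features: mode-based bias estimation is unreliable "
            f"for small feature sizes (m < {SMALL_M_WARN})"
        )
    sqrt_n = np.sqrt(di.n)
    mode, h_used = kde_mode(sqrt_n * alpha_tilde, kernel=kernel, h=h, full_output=True)
    bias = -mode / sqrt_n
    est = BiasEstimate(bias=float(bias), mode_value=float(mode), h=h_used,
                       kernel=kernel, grid_size=1024)
    return alpha_tilde + bias, est
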