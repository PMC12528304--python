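"""Landau (near-critical) analysis of the general-spin Ising mean field.

Expanding the self-consistency map f(mu) around mu = 0 at tau = 0 gives a
linear slope r * beta * sigma * d with the category-dependent factor

    r = (2k+1) / (6k),

which decreases from 1/2 at k = 1 toward 1/3 as k grows: more spin
categories push the transition to lower temperatures.  The critical inverse
temperature is beta_c = 1/(r sigma d); just above it the spontaneous
magnetisation follows mu ~ +-sqrt(r beta sigma d - 1) (exponent 1/2), and on
the critical isotherm mu ~ sign(tau) (|tau|/(r sigma d))^(1/3) (exponent 1/3).
The field value at which a hysteresis branch jumps is estimated by
tau* ~ r sigma d = 1/beta_c.

Regular-Ising convention: the r formula is an integer-k linearisation and
does not apply at k = 1/2, where f = tanh(beta gamma) has unit slope in
beta gamma.  Functions taking k treat k = 1/2 with slope 1 (so beta_c =
1/(sigma d)), labelled "regular" rather than r(1/2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "landau_factor",
    "critical_beta",
    "spontaneous_magnetisation_approx",
    "critical_isotherm_approx",
    "hysteresis_jump_estimate",
    "fit_power_law_exponent",
]


def landau_factor(k) -> float:
    """r = (2k+1)/(6k), the linearisation slope factor of the mean-field map.

    Defined for the integer-k family (it equals the half-set second moment
    that multiplies beta sigma d in f'(0) at tau = 0).  Evaluating at k = 1/2
    returns the printed formula's value, but the regular model's effective
    slope factor is 1; use :func:`critical_beta`, which applies that
    convention.
    """
    kf = float(k)
    if kf <= 0:
        raise ValueError(f"k must be > 0, got {k!r}")
    return (2.0 * kf + 1.0) / (6.0 * kf)


def _slope_factor(k) -> float:
    """Linearisation slope factor: r(k) for integer k, 1 for the regular model."""
    return 1.0 if float(k) == 0.5 else landau_factor(k)


def critical_beta(k, sigma: float, d: float) -> float:
    """beta_c = 1/(r sigma d); the regular model (k = 1/2) uses 1/(sigma d)."""
    if sigma * d <= 0:
        raise ValueError("sigma * d must be > 0: no transition otherwise")
    return 1.0 / (_slope_factor(k) * sigma * d)


def spontaneous_magnetisation_approx(beta: float, k, sigma: float,
                                     d: float) -> tuple[float, float]:
    """Near-critical spontaneous magnetisation branches at tau = 0.

    Returns the pair (-m, +m) with m = sqrt(r beta sigma d - 1) when the
    ordering argument r beta sigma d exceeds 1, and (0, 0) otherwise.
    Valid asymptotically as r beta sigma d decreases to 1.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    arg = _slope_factor(k) * beta * sigma * d
    if arg <= 1.0:
        return (0.0, 0.0)
    m = float(np.sqrt(arg - 1.0))
    return (-m, m)


def critical_isotherm_approx(tau: float, k, sigma: float, d: float) -> float:
    """mu on the critical isotherm: sign(tau) * (|tau| / (r sigma d))^(1/3)."""
    if sigma * d <= 0:
        raise ValueError("sigma * d must be > 0")
    return float(np.sign(tau) * (abs(tau) / (_slope_factor(k) * sigma * d)) ** (1.0 / 3.0))


def hysteresis_jump_estimate(k, sigma: float, d: float) -> float:
    """Estimated positive field at which the magnetisation branch jumps.

    tau* = r sigma d = 1/beta_c; the full loop width estimate is 2 tau*.
    A leading-order Landau estimate — the exact mean-field spinodal lies
    below it, increasingly so deep in the ordered phase.
    """
    if sigma * d <= 0:
        raise ValueError("sigma * d must be > 0")
    return _slope_factor(k) * sigma * d


def fit_power_law_exponent(x, y) -> tuple[float, float, float]:
    """Least-squares slope of log y against log x.

    Returns (slope, intercept, residual) where residual is the sum of squared
    log-space deviations.  Both sequences must be positive, equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d sequences of length >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    (slope, intercept), res = np.polyfit(lx, ly, 1), 0.0
    res = float(((ly - (slope * lx + intercept)) ** 2).sum())
    return float(slope), float(intercept), res
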