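"""Mean-field theory of Ising(k): Gibbs free energy, self-consistency, susceptibility.

The mean-field approximation replaces every node's neighbourhood by the
average field ``d * mu`` (d = mean degree, mu = mean spin), giving a
variational Gibbs free energy per the standard construction

    G(mu) = sigma mu^2 n d / 2
            - (n/beta) log sum_{x in Omega_k+} 2 cosh(beta gamma x),

with effective field gamma = tau + sigma mu d and the sum running over the
nonnegative half of the spin space.  Its stationarity condition is the
self-consistency equation

    mu = f(mu) = [sum_x x sinh(x beta gamma)] / [sum_x cosh(x beta gamma)],

and differentiating f with respect to tau gives the susceptibility

    chi = beta * ( [sum_x x^2 cosh(x beta gamma)] / [sum_x cosh(x beta gamma)] - mu^2 ).

For k = 1/2 the half-set is {1} and f reduces to tanh(beta gamma): the
regular Curie–Weiss mean field.

Note these formulas weight the x=0 term of integer-k sums by 2 cosh(0) = 2
(the half-set sum convention); a single-site Boltzmann average over the full
spin space counts the zero state once and therefore differs.  The mean-field
equations here form a self-consistent variational family (f is exactly the
stationarity condition of G); :func:`single_site_thermal_average` is provided
only as a comparison oracle and is not part of the mean-field API.

All sums are evaluated after factoring out the largest exponential, so the
functions stay finite for k up to a few thousand and beta gamma of order 10^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .model_core import ModelParams, build_spin_space

__all__ = [
    "MeanFieldState",
    "FixedPoint",
    "FixedPointSet",
    "self_consistency_rhs",
    "gibbs_free_energy",
    "susceptibility",
    "iterate_map",
    "find_fixed_points",
    "select_equilibrium",
    "single_site_thermal_average",
]


@dataclass(frozen=True)
class MeanFieldState:
    """One mean-field point: mu, the effective field gamma = tau + sigma mu d, and d."""

    mu: float
    gamma: float
    d: float

    @classmethod
    def from_mu(cls, mu: float, params: ModelParams, d: float) -> "MeanFieldState":
        return cls(mu=mu, gamma=params.tau + params.sigma * mu * d, d=d)


def _scaled_half_sums(mu, params: ModelParams, d: float):
    """Return (num, den, x2num) = scaled sums of x sinh, cosh, x^2 cosh over Omega_k+.

    All three share the common factor exp(max|beta gamma x|), which cancels in
    every ratio the public functions take.  ``mu`` may be a scalar or ndarray.
    """
    xs = build_spin_space(params.k).nonneg
    mu_arr = np.asarray(mu, dtype=float)
    gamma = params.tau + params.sigma * mu_arr * d
    a = params.beta * np.multiply.outer(gamma, xs)  # (..., n_half)
    m = np.abs(a).max(axis=-1, keepdims=True)
    ep = np.exp(a - m)
    em = np.exp(-a - m)
    cosh_s = 0.5 * (ep + em)
    sinh_s = 0.5 * (ep - em)
    num = (xs * sinh_s).sum(axis=-1)
    den = cosh_s.sum(axis=-1)
    x2num = (xs * xs * cosh_s).sum(axis=-1)
    return num, den, x2num, m[..., 0]


def self_consistency_rhs(mu, params: ModelParams, d: float):
    """f(mu): the mean-field map whose fixed points are self-consistent mu.

    Accepts scalar or array ``mu``; output lies strictly inside (-1, 1).
    For k = 1/2 this is tanh(beta (tau + sigma mu d)).
    """
    if d < 0:
        raise ValueError("mean degree d must be >= 0")
    num, den, _, _ = _scaled_half_sums(mu, params, d)
    out = num / den
    return float(out) if np.ndim(mu) == 0 else out


def gibbs_free_energy(mu, params: ModelParams, n: int, d: float):
    """Variational Gibbs free energy G(mu) for an n-node system of mean degree d.

    Requires beta > 0 (the entropic log term is undefined at beta = 0).
    Scalar or array ``mu``.
    """
    if params.beta <= 0:
        raise ValueError("gibbs_free_energy requires beta > 0")
    xs = build_spin_space(params.k).nonneg
    mu_arr = np.asarray(mu, dtype=float)
    gamma = params.tau + params.sigma * mu_arr * d
    a = params.beta * np.multiply.outer(gamma, xs)
    m = np.abs(a).max(axis=-1)
    # stable form: 2cosh(a) = e^m (e^{a-m} + e^{-a-m})
    log_zmu = m + np.log((np.exp(a - m[..., None]) + np.exp(-a - m[..., None])).sum(axis=-1))
    out = params.sigma * mu_arr**2 * n * d / 2.0 - (n / params.beta) * log_zmu
    return float(out) if np.ndim(mu) == 0 else out


def susceptibility(mu, params: ModelParams, d: float):
    """chi = beta ( <x^2>_half - mu^2 ): response of mu to the external field.

    Interpreted as the susceptibility when ``mu`` solves the self-consistency
    equation; the expression is evaluated for any mu.
    """
    _, den, x2num, _ = _scaled_half_sums(mu, params, d)
    mu_arr = np.asarray(mu, dtype=float)
    out = params.beta * (x2num / den - mu_arr**2)
    return float(out) if np.ndim(mu) == 0 else out


def iterate_map(mu0: float, params: ModelParams, d: float, n_steps: int = 1) -> np.ndarray:
    """Iterates mu_{t+1} = f(mu_t) starting from mu0 (cobweb-style analysis).

    Returns the length n_steps+1 orbit including mu0.  Iteration converges
    only to attracting fixed points; use :func:`find_fixed_points` to locate
    repelling ones.
    """
    orbit = np.empty(n_steps + 1)
    orbit[0] = mu0
    for t in range(n_steps):
        orbit[t + 1] = self_consistency_rhs(orbit[t], params, d)
    return orbit


@dataclass(frozen=True)
class FixedPoint:
    mu: float
    stability: Literal["attracting", "repelling"]
    gibbs_value: float
    f_prime: float


@dataclass(frozen=True)
class FixedPointSet:
    """All roots of f(mu) - mu on [-1, 1], sorted ascending in mu."""

    points: tuple[FixedPoint, ...]
    params: ModelParams
    d: float

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def attracting(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.stability == "attracting")

    def mus(self) -> np.ndarray:
        return np.array([p.mu for p in self.points])


_DERIV_STEP = 1e-6


def _classify(mu: float, params: ModelParams, d: float) -> tuple[str, float]:
    lo, hi = mu - _DERIV_STEP, mu + _DERIV_STEP
    fp = (self_consistency_rhs(hi, params, d)
          - self_consistency_rhs(lo, params, d)) / (hi - lo)
    return ("attracting" if abs(fp) < 1.0 else "repelling"), float(fp)


def find_fixed_points(params: ModelParams, d: float,
                      grid: int = 2001, tol: float = 1e-12) -> FixedPointSet:
    """Locate every solution of mu = f(mu) on [-1, 1].

    Sign-change bracketing on a uniform ``grid`` followed by root refinement
    to |f(mu*) - mu*| <= tol; stability from the numerical |f'| against 1;
    the Gibbs free energy (n = 1 normalisation) is attached to each root.
    The default grid is dense enough that no bracket straddles two roots for
    the smooth, bounded maps arising here.
    """
    if d < 0:
        raise ValueError("mean degree d must be >= 0")
    mus = np.linspace(-1.0, 1.0, grid)
    g = self_consistency_rhs(mus, params, d) - mus
    roots: list[float] = []
    for i in range(grid):
        if g[i] == 0.0:
            roots.append(float(mus[i]))
    sign = np.sign(g)
    for i in range(grid - 1):
        if sign[i] * sign[i + 1] < 0:
            fn = lambda m: self_consistency_rhs(m, params, d) - m
            root = brentq(fn, mus[i], mus[i + 1], xtol=1e-15, rtol=8.9e-16)
            if abs(fn(root)) > tol:  # pragma: no cover - brentq is tighter
                raise RuntimeError("fixed-point refinement failed to reach tolerance")
            roots.append(float(root))
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or r - dedup[-1] > 1e-9:
            dedup.append(r)
    pts = []
    for r in dedup:
        stability, fp = _classify(r, params, d)
        gb = gibbs_free_energy(r, params, n=1, d=d) if params.beta > 0 else float("nan")
        pts.append(FixedPoint(mu=r, stability=stability, gibbs_value=gb, f_prime=fp))
    return FixedPointSet(points=tuple(pts), params=params, d=d)


def select_equilibrium(fps: FixedPointSet) -> float:
    """The thermodynamic equilibrium: attracting root of least Gibbs free energy.

    A symmetric tau = 0 pair ties in G; the tie is broken toward the
    non-negative root (documented convention used by the phase maps).
    """
    if not len(fps):
        raise ValueError("empty fixed-point set")
    cands = fps.attracting() or fps.points
    if len(cands) == 1:
        return cands[0].mu
    best_g = min(p.gibbs_value for p in cands)
    tied = [p for p in cands if p.gibbs_value <= best_g + 1e-10 * max(1.0, abs(best_g))]
    return max(p.mu for p in tied)


def single_site_thermal_average(k, beta: float, gamma: float) -> float:
    """Exact one-site Boltzmann average sum_{x in Omega_k} x e^{beta gamma x} / Z_1.

    Comparison oracle only: counts the zero state once and therefore differs
    from :func:`self_consistency_rhs` for integer k (the mean-field family
    weights x = 0 by 2 through its half-set sums).  Not used by any solver.
    """
    xs = build_spin_space(k).values
    a = beta * gamma * xs
    a -= a.max()
    w = np.exp(a)
    return float((xs * w).sum() / w.sum())
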