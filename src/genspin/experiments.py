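"""Experiment drivers: sweeps, hysteresis loops, phase maps, finite-size studies.

These reproduce the model's numerical phenomenology:

* magnetisation versus inverse temperature, mean-field and Monte Carlo,
  with the near-critical square-root law overlaid;
* hysteresis loops in the external field tau, where each point warm-starts
  from the previous one — in mean-field mode the solver follows the
  attracting fixed point nearest the previous mu (basin continuity), which is
  what produces history dependence from a deterministic map;
* hysteresis width as a function of the number of categories 2k+1, which
  shrinks and saturates as k grows;
* beta–tau phase maps of the global Gibbs equilibrium (single-valued: no
  metastable branches — only the hysteresis driver follows those);
* finite-size / degree studies of the gap between Monte Carlo and mean field.

Every driver is a pure function of (parameters, seeds): per-point chain seeds
are derived from one SeedSequence, so reruns are bit-identical.  Mean-field
columns depend only on the nominal mean degree d (for Erdős–Rényi input,
d = p_e (n - 1)), never on a sampled graph or seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .landau import critical_beta, spontaneous_magnetisation_approx
from .mean_field import FixedPointSet, find_fixed_points, select_equilibrium
from .model_core import InteractionGraph, ModelParams
from .montecarlo import MCConfig, erdos_renyi, magnetisation_estimate, metropolis_run

__all__ = [
    "SweepResult",
    "HysteresisResult",
    "temperature_sweep",
    "field_sweep_hysteresis",
    "hysteresis_width_vs_k",
    "phase_map",
    "finite_size_study",
    "PRESETS",
]

logger = logging.getLogger(__name__)

#: named parameter presets mirroring the regimes studied in the source figures
PRESETS: dict[str, dict] = {
    # double-well free energy / three fixed points
    "double-well": dict(k=3, beta=3.0, sigma=1.0, tau=0.3, d=2.0),
    # mean-field temperature sweep at zero field
    "tsweep": dict(k=3, beta=1.0, sigma=0.1, tau=0.0, d=10.0),
    # beta-tau phase map
    "phasemap": dict(k=3, beta=1.0, sigma=1.0, tau=0.0, d=2.0),
    # Monte Carlo temperature sweep on an ER graph
    "mc-tsweep": dict(k=3, beta=1.0, sigma=0.1, tau=0.0, n=100, p_e=0.1),
    # deep-ordered hysteresis loop regime (supercritical for every k >= 1/2)
    "hysteresis": dict(k=3, beta=5.0, sigma=0.1, tau=0.0, n=100, p_e=0.1),
}


def _derive_seeds(seed: int, count: int) -> list[int]:
    """Deterministic per-point chain seeds below 2^31."""
    state = np.random.SeedSequence(int(seed)).generate_state(count, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class SweepResult:
    """Tidy sweep output: control-parameter grid vs magnetisation columns."""

    control: str
    grid: np.ndarray = field(repr=False)
    mean_field: np.ndarray = field(repr=False)
    landau: np.ndarray | None = field(default=None, repr=False)
    mc_mean: np.ndarray | None = field(default=None, repr=False)
    mc_se: np.ndarray | None = field(default=None, repr=False)
    mc_seeds: np.ndarray | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {self.control: self.grid, "mean_field": self.mean_field}
        if self.landau is not None:
            cols["landau"] = self.landau
        if self.mc_mean is not None:
            cols["mc_mean"] = self.mc_mean
            cols["mc_se"] = self.mc_se
            cols["mc_seed"] = self.mc_seeds
        return pd.DataFrame(cols)


def _nominal_degree(d=None, n=None, p_e=None, graph=None) -> float:
    if d is not None:
        return float(d)
    if n is not None and p_e is not None:
        return float(p_e) * (n - 1)
    if graph is not None:
        return graph.mean_degree
    raise ValueError("provide d, (n, p_e), or a graph")


def temperature_sweep(beta_grid, params: ModelParams, *,
                      d: float | None = None, n: int | None = None,
                      p_e: float | None = None,
                      graph: InteractionGraph | None = None,
                      mc: MCConfig | None = None,
                      graph_seed: int = 0) -> SweepResult:
    """|mu| versus beta: mean-field equilibrium, Landau overlay, optional MC.

    The mean-field column uses the global Gibbs equilibrium at the nominal
    mean degree.  The MC column reports mean |m| on one shared graph across
    the whole grid (finite symmetric systems have m ~ 0 but |m| > 0).
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0:
        raise ValueError("beta_grid must be non-empty")
    dd = _nominal_degree(d, n, p_e, graph)
    mf = np.empty_like(beta_grid)
    for i, b in enumerate(beta_grid):
        fps = find_fixed_points(params.replace(beta=float(b)), dd)
        mf[i] = abs(select_equilibrium(fps))
    lan = np.array([
        spontaneous_magnetisation_approx(b, params.k, params.sigma, dd)[1]
        for b in beta_grid])
    mc_mean = mc_se = seeds_arr = None
    meta = dict(params=dataclasses.asdict(params), d=dd)
    if mc is not None:
        if graph is None:
            if n is None or p_e is None:
                raise ValueError("MC sweep needs a graph or (n, p_e)")
            graph = erdos_renyi(n, p_e, graph_seed)
        meta["realised_mean_degree"] = graph.mean_degree
        seeds = _derive_seeds(mc.seed, beta_grid.size)
        mc_mean = np.empty_like(beta_grid)
        mc_se = np.empty_like(beta_grid)
        for i, b in enumerate(beta_grid):
            traj = metropolis_run(graph, params.replace(beta=float(b)),
                                  dataclasses.replace(mc, seed=seeds[i]))
            mc_mean[i], mc_se[i] = magnetisation_estimate(np.abs(traj.magnetisation))
        seeds_arr = np.array(seeds)
    return SweepResult(control="beta", grid=beta_grid, mean_field=mf,
                       landau=lan, mc_mean=mc_mean, mc_se=mc_se,
                       mc_seeds=seeds_arr, metadata=meta)


@dataclass(frozen=True)
class HysteresisResult:
    """Up- and down-sweep branches with detected jump locations.

    ``tau_up``/``tau_down`` are None when no jump exceeds the threshold
    (subcritical temperatures give a single-valued curve, width 0).
    """

    up: SweepResult
    down: SweepResult
    tau_up: float | None
    tau_down: float | None

    @property
    def width(self) -> float:
        if self.tau_up is None or self.tau_down is None:
            return 0.0
        return self.tau_up - self.tau_down


def _nearest_attracting(fps: FixedPointSet, mu_prev: float) -> float:
    cands = fps.attracting() or fps.points
    return min(cands, key=lambda p: abs(p.mu - mu_prev)).mu


def _detect_jump(taus: np.ndarray, ms: np.ndarray, threshold: float) -> float | None:
    dm = np.abs(np.diff(ms))
    if dm.size == 0 or dm.max() <= threshold:
        return None
    i = int(np.argmax(dm))
    return float(0.5 * (taus[i] + taus[i + 1]))


def field_sweep_hysteresis(params: ModelParams, *,
                           d: float | None = None,
                           tau_min: float = -0.5, tau_max: float = 0.5,
                           step: float = 0.01,
                           graph: InteractionGraph | None = None,
                           mc: MCConfig | None = None,
                           jump_threshold: float = 0.2,
                           grid: int = 2001) -> HysteresisResult:
    """Sweep tau up then down with warm starts; detect branch jumps.

    Mean-field mode (no ``mc``): at each tau the solver keeps the attracting
    fixed point nearest the previous mu, so the trajectory follows a
    metastable branch until it disappears at the spinodal.  MC mode re-starts
    each chain from the previous final configuration; its signed mean m is
    reported.  Jumps are |dm| > jump_threshold between consecutive steps;
    the jump location is the midpoint of the straddling pair.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    dd = _nominal_degree(d, graph=graph)
    taus_up = np.arange(tau_min, tau_max + step / 2, step)
    taus_down = taus_up[::-1].copy()
    meta = dict(params=dataclasses.asdict(params), d=dd, step=step,
                jump_threshold=jump_threshold)

    def mf_branch(taus: np.ndarray, mu_start: float) -> np.ndarray:
        out = np.empty_like(taus)
        mu = mu_start
        for i, t in enumerate(taus):
            fps = find_fixed_points(params.replace(tau=float(t)), dd, grid=grid)
            mu = _nearest_attracting(fps, mu)
            out[i] = mu
        return out

    if mc is None:
        fps0 = find_fixed_points(params.replace(tau=float(taus_up[0])), dd, grid=grid)
        m_up = mf_branch(taus_up, select_equilibrium(fps0))
        m_down = mf_branch(taus_down, m_up[-1])
        up = SweepResult("tau", taus_up, m_up, metadata=meta)
        down = SweepResult("tau", taus_down, m_down, metadata=meta)
    else:
        if graph is None:
            raise ValueError("MC hysteresis needs a graph")
        seeds = _derive_seeds(mc.seed, 2 * taus_up.size)

        def mc_branch(taus, init, seed_off):
            ms = np.empty_like(taus)
            ses = np.empty_like(taus)
            cfg = init
            for i, t in enumerate(taus):
                run = dataclasses.replace(mc, seed=seeds[seed_off + i], init=cfg)
                traj = metropolis_run(graph, params.replace(tau=float(t)), run)
                ms[i], ses[i] = magnetisation_estimate(traj)
                cfg = traj.final_config
            return ms, ses

        space = params.spin_space()
        m_up, se_up = mc_branch(taus_up, np.full(graph.n, space.values[0]), 0)
        m_down, se_down = mc_branch(taus_down, np.full(graph.n, space.values[-1]),
                                    taus_up.size)
        up = SweepResult("tau", taus_up, m_up, mc_mean=m_up, mc_se=se_up,
                         metadata=meta)
        down = SweepResult("tau", taus_down, m_down, mc_mean=m_down,
                           mc_se=se_down, metadata=meta)

    tau_up = _detect_jump(up.grid, up.mean_field, jump_threshold)
    tau_down = _detect_jump(down.grid, down.mean_field, jump_threshold)
    if tau_up is None or tau_down is None:
        logger.info("no hysteresis jump detected (subcritical regime); width 0")
    return HysteresisResult(up=up, down=down, tau_up=tau_up, tau_down=tau_down)


def hysteresis_width_vs_k(k_list: Sequence, params: ModelParams, *,
                          d: float, tau_min: float = -0.8,
                          tau_max: float = 0.8, step: float = 0.01,
                          grid: int = 2001,
                          jump_threshold: float = 0.2) -> pd.DataFrame:
    """Mean-field hysteresis width per k under one identical protocol.

    Returns a table (k, width, tau_up, tau_down, delta_width) where
    delta_width is the successive difference, exhibiting saturation as the
    number of categories grows.
    """
    rows = []
    for k in k_list:
        res = field_sweep_hysteresis(
            params.replace(k=k), d=d, tau_min=tau_min, tau_max=tau_max,
            step=step, grid=grid, jump_threshold=jump_threshold)
        rows.append(dict(k=k, width=res.width, tau_up=res.tau_up,
                         tau_down=res.tau_down))
    out = pd.DataFrame(rows)
    out["delta_width"] = out["width"].diff()
    return out


def phase_map(beta_grid, tau_grid, params: ModelParams, *, d: float,
              grid: int = 2001) -> pd.DataFrame:
    """Equilibrium magnetisation over the (beta, tau) plane, tidy long form.

    Uses the global Gibbs minimiser per cell (signed), columns
    (beta, tau, mu_star).  Single-valued by construction; at tau = 0 the
    symmetric tie is broken toward the non-negative root.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if beta_grid.size == 0 or tau_grid.size == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for b in beta_grid:
        for t in tau_grid:
            fps = find_fixed_points(params.replace(beta=float(b), tau=float(t)),
                                    d, grid=grid)
            rows.append(dict(beta=float(b), tau=float(t),
                             mu_star=select_equilibrium(fps)))
    return pd.DataFrame(rows)


def finite_size_study(n_list: Sequence[int], pe_list: Sequence[float],
                      beta_grid, params: ModelParams, *,
                      mc: MCConfig, seed: int = 0, n_seeds: int = 2,
                      relative_to_critical: bool = True
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MC-versus-mean-field accuracy across system sizes and edge densities.

    Runs every (n, p_e) pair in the cross product.  With
    ``relative_to_critical`` (default) the ``beta_grid`` entries are
    multiples of each curve's own beta_c = 1/(r sigma d), d = p_e (n - 1),
    so curves are compared at matched distances from criticality; otherwise
    the grid is absolute.  Each point averages mean |m| over ``n_seeds``
    independent graphs and chains.

    Returns ``(table, summary)``: the long-form table has one row per
    (n, p_e, beta, seed); the summary has the per-curve deviation
    max_beta |mc - mean_field|, the accuracy figure of merit.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if any(n < 2 for n in n_list):
        raise ValueError("all n must be >= 2")
    rows = []
    summaries = []
    curves = [(int(n), float(pe)) for n in n_list for pe in pe_list]
    seeds = _derive_seeds(seed, 2 * len(curves) * beta_grid.size * n_seeds)
    si = 0
    for n, pe in curves:
        dd = pe * (n - 1)
        betas = (beta_grid * critical_beta(params.k, params.sigma, dd)
                 if relative_to_critical else beta_grid)
        gaps = []
        for j, b in enumerate(betas):
            pb = params.replace(beta=float(b))
            mf = abs(select_equilibrium(find_fixed_points(pb, dd)))
            mc_vals = []
            for rep in range(n_seeds):
                gseed, cseed = seeds[si], seeds[si + 1]
                si += 2
                graph = erdos_renyi(n, pe, gseed)
                traj = metropolis_run(graph, pb,
                                      dataclasses.replace(mc, seed=cseed))
                est, se = magnetisation_estimate(np.abs(traj.magnetisation))
                mc_vals.append(est)
                rows.append(dict(n=n, p_e=pe, beta=float(b),
                                 beta_over_beta_c=float(beta_grid[j])
                                 if relative_to_critical else np.nan,
                                 mean_field=mf, mc_abs_m=est, mc_se=se,
                                 graph_seed=gseed, chain_seed=cseed))
            gaps.append(abs(float(np.mean(mc_vals)) - mf))
        summaries.append(dict(n=n, p_e=pe, d=dd,
                              max_abs_gap=float(np.max(gaps))))
    return pd.DataFrame(rows), pd.DataFrame(summaries)
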