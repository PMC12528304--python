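"""Single-site Metropolis sampling of Ising(k) on Erdős–Rényi graphs.

Each update picks a node uniformly at random, proposes a replacement spin
uniformly from all 2k+1 values (including the current one — a symmetric
proposal, valid for Metropolis at any k), and accepts with probability
min(1, exp(-beta dH)).  dH is computed locally from the node's field term and
its neighbour sum, so one update costs O(degree).  The chain's stationary
distribution is the Boltzmann law of the model, which the test suite checks
against exact enumeration on small systems.

One *sweep* is n proposed updates.  Randomness is pre-generated per chunk of
sweeps from a single seeded generator, and the inner loop is compiled with
numba when available; the pure-Python path consumes the identical streams, so
trajectories are bit-identical either way.  Graph generation takes its own
seed, so one graph can be reused across a range of temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Union

import networkx as nx
import numpy as np

from .model_core import (
    InteractionGraph,
    ModelParams,
    config_to_indices,
    hamiltonian,
)

__all__ = [
    "MCConfig",
    "Trajectory",
    "erdos_renyi",
    "metropolis_run",
    "magnetisation_estimate",
]

logger = logging.getLogger(__name__)


def erdos_renyi(n: int, p_e: float, seed: int) -> InteractionGraph:
    """G(n, p_e): each unordered pair is an edge independently with prob p_e.

    Expected mean degree d = p_e (n - 1); the realised mean degree is on the
    returned graph.
    """
    if not 0.0 <= p_e <= 1.0:
        raise ValueError(f"p_e must be in [0, 1], got {p_e}")
    if n < 1:
        raise ValueError("n must be >= 1")
    g = nx.fast_gnp_random_graph(n, p_e, seed=int(seed))
    return InteractionGraph.from_networkx(g)


@dataclass(frozen=True)
class MCConfig:
    """Metropolis run protocol.

    n_sweeps : total sweeps simulated (one sweep = n single-site proposals)
    burn_in : sweeps discarded before recording
    thin : record every thin-th sweep after burn-in
    seed : chain RNG seed (independent of the graph seed)
    init : 'random' | 'up' | 'down' | explicit spin-value sequence
    """

    n_sweeps: int = 5000
    burn_in: int = 500
    seed: int = 0
    thin: int = 1
    init: Union[str, Sequence[float]] = "random"

    def __post_init__(self):
        if not (self.n_sweeps > self.burn_in >= 0):
            raise ValueError("need n_sweeps > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Recorded chain output: per-recorded-sweep magnetisation and energy."""

    magnetisation: np.ndarray = field(repr=False)
    energy: np.ndarray = field(repr=False)
    acceptance_rate: float
    final_config: np.ndarray = field(repr=False)
    config_ids: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.magnetisation)


def _sweep_chunk_py(spin_idx, values, indptr, indices, beta, sigma, tau,
                    nodes, props, logu, n_sweeps, n, out_m, out_e, S, E):
    """Reference chunk kernel; vectorised neighbour sums, same update order
    and RNG consumption as the compiled kernel."""
    acc = 0
    t = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            s = nodes[t]
            j_new = props[t]
            j_old = spin_idx[s]
            if j_new == j_old:
                acc += 1
            else:
                nb = indices[indptr[s]:indptr[s + 1]]
                nb_sum = values[spin_idx[nb]].sum() if len(nb) else 0.0
                de = -(tau + sigma * nb_sum) * (values[j_new] - values[j_old])
                if de <= 0.0 or logu[t] < -beta * de:
                    S += values[j_new] - values[j_old]
                    E += de
                    spin_idx[s] = j_new
                    acc += 1
            t += 1
        out_m[sweep] = S / n
        out_e[sweep] = E
    return S, E, acc


def _sweep_chunk_loops(spin_idx, values, indptr, indices, beta, sigma, tau,
                       nodes, props, logu, n_sweeps, n, out_m, out_e, S, E):
    # scalar-loop variant, written to compile under numba.njit
    acc = 0
    t = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            s = nodes[t]
            j_new = props[t]
            j_old = spin_idx[s]
            if j_new == j_old:
                acc += 1
            else:
                nb_sum = 0.0
                for ptr in range(indptr[s], indptr[s + 1]):
                    nb_sum += values[spin_idx[indices[ptr]]]
                de = -(tau + sigma * nb_sum) * (values[j_new] - values[j_old])
                if de <= 0.0 or logu[t] < -beta * de:
                    S += values[j_new] - values[j_old]
                    E += de
                    spin_idx[s] = j_new
                    acc += 1
            t += 1
        out_m[sweep] = S / n
        out_e[sweep] = E
    return S, E, acc


try:  # compiled kernel if numba is present; falls back transparently
    from numba import njit as _njit

    _sweep_chunk = _njit(cache=True, nogil=True)(_sweep_chunk_loops)
except ImportError:  # pragma: no cover - exercised only without numba
    _sweep_chunk = _sweep_chunk_py


def _initial_indices(mc: MCConfig, graph: InteractionGraph,
                     params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    space = params.spin_space()
    if isinstance(mc.init, str):
        if mc.init == "random":
            return rng.integers(0, space.size, graph.n, dtype=np.int64)
        if mc.init == "up":
            return np.full(graph.n, space.size - 1, dtype=np.int64)
        if mc.init == "down":
            return np.zeros(graph.n, dtype=np.int64)
        raise ValueError(f"unknown init {mc.init!r}")
    return config_to_indices(mc.init, space)


def metropolis_run(graph: InteractionGraph, params: ModelParams, mc: MCConfig,
                   chunk_sweeps: int = 256,
                   record_configs: bool = False) -> Trajectory:
    """Run the single-site Metropolis chain and record after burn-in.

    ``record_configs=True`` additionally stores the odometer config id of
    every recorded sweep (small systems only: requires (2k+1)^n to fit an
    int64), which the distribution tests compare against exact enumeration.
    """
    space = params.spin_space()
    values = space.values.astype(np.float64)
    indptr, indices = graph.adjacency_csr()
    rng = np.random.default_rng(mc.seed)
    spin_idx = _initial_indices(mc, graph, params, rng)
    n = graph.n
    q = space.size

    S = float(values[spin_idx].sum())
    E = hamiltonian(values[spin_idx], graph, params)
    m_all = np.empty(mc.n_sweeps)
    e_all = np.empty(mc.n_sweeps)
    ids_all = np.empty(mc.n_sweeps, dtype=np.int64) if record_configs else None
    if record_configs:
        if q ** n > np.iinfo(np.int64).max:
            raise ValueError("system too large to record config ids")
        weights = q ** np.arange(n - 1, -1, -1, dtype=np.int64)
        chunk_sweeps = 1  # snapshot after every sweep
    acc_total = 0
    done = 0
    while done < mc.n_sweeps:
        todo = min(chunk_sweeps, mc.n_sweeps - done)
        total = todo * n
        nodes = rng.integers(0, n, total, dtype=np.int64)
        props = rng.integers(0, q, total, dtype=np.int64)
        logu = np.log(rng.random(total))
        S, E, acc = _sweep_chunk(
            spin_idx, values, indptr, indices,
            float(params.beta), float(params.sigma), float(params.tau),
            nodes, props, logu, todo, n,
            m_all[done:done + todo], e_all[done:done + todo], S, E,
        )
        if record_configs:
            ids_all[done] = int(np.dot(spin_idx, weights))
        acc_total += acc
        done += todo

    sl = slice(mc.burn_in, None, mc.thin)
    return Trajectory(
        magnetisation=m_all[sl].copy(),
        energy=e_all[sl].copy(),
        acceptance_rate=acc_total / (mc.n_sweeps * n),
        final_config=values[spin_idx].copy(),
        config_ids=ids_all[sl].copy() if record_configs else None,
    )


def magnetisation_estimate(traj: Trajectory | np.ndarray,
                           n_batches: int = 20) -> tuple[float, float]:
    """Time-average magnetisation and a batch-means standard error.

    Batch means (default 20 contiguous batches) absorb autocorrelation; with
    fewer records than batches the naive i.i.d. SE is used and a warning
    logged.
    """
    m = traj.magnetisation if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if len(m) == 0:
        raise ValueError("empty trajectory")
    mean = float(m.mean())
    if len(m) < n_batches:
        logger.warning(
            "only %d records for %d batches; falling back to naive SE",
            len(m), n_batches)
        se = float(m.std(ddof=1) / np.sqrt(len(m))) if len(m) > 1 else 0.0
        return mean, se
    usable = (len(m) // n_batches) * n_batches
    batches = m[:usable].reshape(n_batches, -1).mean(axis=1)
    se = float(batches.std(ddof=1) / np.sqrt(n_batches))
    return mean, se
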