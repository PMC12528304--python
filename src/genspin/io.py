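"""Run configuration (YAML), validation, and sweep serialisation.

A run config is structured text with up to four blocks plus a seed::

    model:      {k: 3, beta: 3, sigma: 1, tau: 0.3}
    graph:      {degree: 2}            # or {n: 100, p_e: 0.1} or {edge_list: path}
    mc:         {n_sweeps: 5000, burn_in: 500, thin: 1, init: random}
    experiment: {name: tsweep, ...}
    seed:       1

For convenience the model keys (and ``degree``) may also be given flat at the
top level.  Unknown keys are rejected by name; every field is validated
against the owning module's preconditions before any computation runs.

Tabular results are written as CSV (the single interchange format; floats
round-trip exactly through Python's repr) with a JSON sidecar carrying full
provenance: parameters, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import HysteresisResult, SweepResult
from .model_core import ModelParams
from .montecarlo import MCConfig

__all__ = ["RunConfig", "load_config", "write_sweep", "read_sweep"]

_MODEL_KEYS = {"k", "beta", "sigma", "tau"}
_GRAPH_KEYS = {"n", "p_e", "degree", "edge_list"}
_MC_KEYS = {"n_sweeps", "burn_in", "thin", "seed", "init"}
_EXPERIMENT_KEYS = {
    "name", "beta_grid", "tau_grid", "tau_min", "tau_max", "step",
    "jump_threshold", "k_list", "n_list", "pe_list", "n_seeds",
    "relative_to_critical", "preset",
}
_TOP_KEYS = {"model", "graph", "mc", "experiment", "seed"} | _MODEL_KEYS | {"degree"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run specification assembled from a config file."""

    params: ModelParams
    degree: float | None = None
    n: int | None = None
    p_e: float | None = None
    edge_list: str | None = None
    mc: MCConfig | None = None
    experiment: dict | None = None
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; raises ValueError naming the
    offending field on any violation."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    model = dict(raw.get("model") or {})
    _check_keys(model, _MODEL_KEYS, "model block")
    for key in _MODEL_KEYS:  # flat keys allowed, block takes precedence
        if key in raw and key not in model:
            model[key] = raw[key]
    missing = _MODEL_KEYS - set(model)
    if missing:
        raise ValueError(f"model block missing key(s): {sorted(missing)}")
    params = ModelParams(beta=float(model["beta"]), sigma=float(model["sigma"]),
                         tau=float(model["tau"]), k=model["k"])

    graph = dict(raw.get("graph") or {})
    _check_keys(graph, _GRAPH_KEYS, "graph block")
    if "degree" in raw and "degree" not in graph:
        graph["degree"] = raw["degree"]
    p_e = graph.get("p_e")
    if p_e is not None and not 0.0 <= float(p_e) <= 1.0:
        raise ValueError(f"p_e must be in [0, 1], got {p_e}")
    n = graph.get("n")
    if n is not None and int(n) < 1:
        raise ValueError(f"n must be >= 1, got {n}")

    mc_block = raw.get("mc")
    mc = None
    if mc_block is not None:
        _check_keys(mc_block, _MC_KEYS, "mc block")
        mc = MCConfig(**mc_block)

    exp = raw.get("experiment")
    if exp is not None:
        _check_keys(exp, _EXPERIMENT_KEYS, "experiment block")

    return RunConfig(
        params=params,
        degree=float(graph["degree"]) if "degree" in graph else None,
        n=int(n) if n is not None else None,
        p_e=float(p_e) if p_e is not None else None,
        edge_list=graph.get("edge_list"),
        mc=mc,
        experiment=dict(exp) if exp is not None else None,
        seed=int(raw.get("seed", 0)),
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_sweep(result: SweepResult | HysteresisResult, path) -> None:
    """Write a sweep (or hysteresis pair) as CSV plus a JSON provenance sidecar.

    Hysteresis results are stacked with a ``direction`` column (up/down).
    The sidecar ``<path>.meta.json`` records parameters, seeds, jump
    locations and the package version; when no MC columns exist it notes the
    run was mean-field only.
    """
    from . import __version__

    path = Path(path)
    if isinstance(result, HysteresisResult):
        up = result.up.to_frame().assign(direction="up")
        down = result.down.to_frame().assign(direction="down")
        frame = pd.concat([up, down], ignore_index=True)
        meta = dict(result.up.metadata)
        meta.update(tau_up=result.tau_up, tau_down=result.tau_down,
                    width=result.width)
        mc_only = result.up.mc_mean is None
    else:
        frame = result.to_frame()
        meta = dict(result.metadata)
        mc_only = result.mc_mean is None
    meta["mean_field_only"] = bool(mc_only)
    meta["version"] = __version__
    meta["columns"] = list(frame.columns)
    frame.to_csv(path, index=False)
    Path(f"{path}.meta.json").write_text(json.dumps(_jsonable(meta), indent=2))


def read_sweep(path) -> pd.DataFrame:
    return pd.read_csv(path)
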