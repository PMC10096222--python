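"""Configuration files, overrides, and run manifests.

Configs are flat key-value mappings in YAML (JSON is valid YAML, so either
dialect works).  Keys mirror the dataclass field names exactly; unknown keys
are rejected so typos fail loudly.  Every CLI run writes a ``manifest.json``
recording the fully resolved configuration and seeds, which is sufficient to
reproduce its artifacts bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import metadata
from pathlib import Path

import networkx as nx
import yaml

from .fixtures import build_toy_graph, make_stand_in_networks
from .grid import GridSpec
from .habituation import HabituationParams
from .network import generate_graph, read_edge_list, read_graphml
from .simulate import SimulationConfig
from .util import derive_seed

__all__ = [
    "ConfigError",
    "load_config",
    "apply_overrides",
    "build_simulation_config",
    "build_grid_spec",
    "load_graph",
    "write_manifest",
]


class ConfigError(ValueError):
    """Invalid configuration file or override."""


#: keys accepted by ``habsi simulate`` configs
SIM_KEYS = {
    "pp", "seed_fraction", "ranking", "habituation_enabled", "recovery_enabled",
    "coverage_target", "max_steps", "rng_seed", "strict_inequality",
    "S", "alpha", "tau", "y0",
}
GRAPH_KEYS = {"graph", "model", "n", "p", "m", "k", "graph_seed"}

#: keys accepted by ``habsi grid`` configs
GRID_KEYS = {
    "rankings", "networks", "pps", "sps", "habituation", "alphas", "taus",
    "replicates", "base_rng_seed", "coverage_target", "max_steps",
}


def load_config(path: str | Path) -> dict:
    """Load a flat key-value config (YAML/JSON dialect)."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping, got {type(data).__name__}")
    return data


def apply_overrides(cfg: dict, overrides) -> dict:
    """Apply repeatable ``key=value`` overrides; values parsed as YAML scalars."""
    out = dict(cfg)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, _, raw = item.partition("=")
        out[key.strip()] = yaml.safe_load(raw.strip())
    return out


def _check_keys(cfg: dict, allowed: set) -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")


def build_simulation_config(cfg: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat mapping (graph keys ignored)."""
    _check_keys(cfg, SIM_KEYS | GRAPH_KEYS)
    hab_kwargs = {k: cfg[k] for k in ("S", "alpha", "tau", "y0") if k in cfg}
    sim_kwargs = {k: cfg[k] for k in SIM_KEYS - {"S", "alpha", "tau", "y0"} if k in cfg}
    try:
        return SimulationConfig(hab_params=HabituationParams(**hab_kwargs), **sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def build_grid_spec(cfg: dict) -> GridSpec:
    """Build a :class:`GridSpec` from a flat mapping; list-valued factors."""
    _check_keys(cfg, GRID_KEYS)
    kwargs = {}
    for key, value in cfg.items():
        kwargs[key] = tuple(value) if isinstance(value, (list, tuple)) else value
    try:
        return GridSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_graph(cfg: dict) -> nx.Graph:
    """Resolve the graph source named by a simulate config.

    ``graph`` may be ``toy`` (bundled fixture), ``standin:i`` (bundled
    synthetic stand-in i, seeded from ``graph_seed``), a ``.graphml`` path, or
    an edge-list path.  Alternatively ``model`` plus its parameters generates
    a synthetic graph.
    """
    if "graph" in cfg:
        label = str(cfg["graph"])
        if label == "toy":
            return build_toy_graph()
        if label.startswith("standin:"):
            seed = derive_seed("networks", cfg.get("graph_seed", 0))
            return make_stand_in_networks(seed)[int(label.split(":", 1)[1]) - 1]
        path = Path(label)
        return read_graphml(path) if path.suffix == ".graphml" else read_edge_list(path)
    if "model" in cfg:
        params = {k: cfg[k] for k in ("n", "p", "m", "k") if k in cfg}
        return generate_graph(cfg["model"], rng_seed=cfg.get("graph_seed", 0), **params)
    raise ConfigError("config must name a graph source ('graph' or 'model')")


def write_manifest(outdir: str | Path, command: str, resolved: dict) -> Path:
    """Record the fully resolved config + package version next to the artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("habsi")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    payload = {"command": command, "habsi_version": version, "config": resolved}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path


def resolved_simulation_dict(cfg: SimulationConfig) -> dict:
    """Flat dict of a simulation config, for manifests."""
    d = asdict(cfg)
    d.update(d.pop("hab_params"))
    return d
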