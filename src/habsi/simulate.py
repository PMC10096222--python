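"""Discrete-time SI contagion with per-contact habituation.

The process runs on a simple undirected graph.  At step 0 a seed set is
infected; in every later step each node infected *before* that step (SI
spreaders never deactivate) attempts to transmit to each of its currently
susceptible neighbours.  One uniform draw is consumed per contact and the
attempt succeeds when the draw is at or below the effective probability
``PP * R(v)``, where ``R(v)`` is the target's responsiveness.  Every failed
attempt habituates the target immediately, so later contacts within the same
step already face the reduced responsiveness.  Nodes infected during step s
first spread in step s+1.  A run stops when coverage (infected fraction,
seeds included) reaches the coverage target, or at the step cap.

Randomness is split into two independent streams derived from the run seed:
one for the per-step shuffles of spreader and neighbour order, one for the
per-contact uniforms.  Exactly one uniform is consumed per contact whether or
not habituation is enabled, so a habituation-free run and a run with
numerically negligible habituation are draw-for-draw identical, and a run can
be replayed exactly from its recorded uniforms.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import networkx as nx
import pandas as pd

from .habituation import HabituationParams

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "Trajectory",
    "select_seeds",
    "initialize_state",
    "run_step",
    "run",
    "duration_to_coverage",
    "mean_responsiveness",
]

#: phase codes used in the dense per-node arrays
_PH_BASELINE, _PH_DECREASING, _PH_RECOVERING = 0, 1, 2

TARGET_REACHED = "target_reached"
MAX_STEPS = "max_steps"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one SI run.

    ``pp`` is the base propagation probability per contact, ``seed_fraction``
    the fraction of nodes infected at step 0 (``random`` uniform sample or
    ``degree`` top-degree ranking), and ``hab_params`` the habituation
    kinetics applied when ``habituation_enabled``.  ``recovery_enabled`` turns
    on quiet-period recovery of responsiveness (off by default: SI spreaders
    attack every step, so quiet periods essentially never occur).
    ``strict_inequality`` switches the activation rule from draw <= threshold
    (the default, matching the documented worked trace where an exactly-equal
    draw activates) to draw < threshold, for sensitivity checks.
    """

    pp: float = 0.1
    seed_fraction: float = 0.01
    ranking: str = "random"
    habituation_enabled: bool = True
    hab_params: HabituationParams = field(default_factory=HabituationParams)
    recovery_enabled: bool = False
    coverage_target: float = 0.80
    max_steps: int = 1000
    rng_seed: int = 0
    strict_inequality: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.pp <= 1:
            raise ValueError(f"pp must be in [0, 1], got {self.pp}")
        if not 0 < self.seed_fraction <= 1:
            raise ValueError(f"seed_fraction must be in (0, 1], got {self.seed_fraction}")
        if self.ranking not in ("random", "degree"):
            raise ValueError(f"ranking must be 'random' or 'degree', got {self.ranking!r}")
        if not 0 < self.coverage_target <= 1:
            raise ValueError(f"coverage_target must be in (0, 1], got {self.coverage_target}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")


def _stream(tag: str, seed: int) -> random.Random:
    """Independent named RNG stream for a given run seed."""
    return random.Random(f"habsi:{tag}:{seed}")


def select_seeds(g: nx.Graph, fraction: float, ranking: str, rng_seed: int) -> list:
    """Choose the step-0 infected set.

    ``k = max(1, round(fraction * |V|))`` nodes (round half up).  Degree
    ranking takes the k highest-degree nodes, ties broken by ascending node
    identifier; random ranking samples uniformly without replacement from a
    dedicated seeded stream.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot seed an empty graph")
    if not 0 < fraction <= 1:
        raise ValueError(f"seed fraction must be in (0, 1], got {fraction}")
    k = max(1, math.floor(fraction * n + 0.5))
    nodes = list(g.nodes())
    if ranking == "degree":
        return sorted(nodes, key=lambda v: (-g.degree(v), str(v)))[:k]
    if ranking == "random":
        return _stream("seeds", rng_seed).sample(nodes, k)
    raise ValueError(f"unknown ranking {ranking!r}")


@dataclass
class SimulationState:
    """Dense per-node state of a running simulation.

    Node labels are mapped to indices 0..n-1 (order of ``g.nodes()``); the
    habituation state machine is held as parallel arrays (failure count,
    responsiveness, phase code, recovery bookkeeping).  Infected nodes keep the
    responsiveness they had at infection time, frozen.  ``sum_y_all`` and
    ``sum_y_infected`` are maintained incrementally so per-step mean
    responsiveness costs O(1).
    """

    nodes: list
    adj: list
    infected: list
    infected_order: list
    c: list
    y: list
    phase: list
    y1: list
    rec_elapsed: list
    newly_infected: list
    step_index: int
    sum_y_all: float
    sum_y_infected: float
    contacts_last_step: int = 0
    failures_last_step: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_infected(self) -> int:
        return len(self.infected_order)

    @property
    def coverage(self) -> float:
        return self.n_infected / self.n_nodes


def initialize_state(g: nx.Graph, cfg: SimulationConfig) -> SimulationState:
    """Build the step-0 state: adjacency indexed densely, seeds infected."""
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[w] for w in g.neighbors(v)] for v in nodes]
    n = len(nodes)
    y0 = cfg.hab_params.y0
    seeds = [index[v] for v in select_seeds(g, cfg.seed_fraction, cfg.ranking, cfg.rng_seed)]
    infected = [False] * n
    for i in seeds:
        infected[i] = True
    return SimulationState(
        nodes=nodes,
        adj=adj,
        infected=infected,
        infected_order=list(seeds),
        c=[0] * n,
        y=[y0] * n,
        phase=[_PH_BASELINE] * n,
        y1=[0.0] * n,
        rec_elapsed=[0] * n,
        newly_infected=list(seeds),
        step_index=0,
        sum_y_all=y0 * n,
        sum_y_infected=y0 * len(seeds),
    )


def run_step(
    state: SimulationState,
    cfg: SimulationConfig,
    shuffle_rng: random.Random,
    uniform: Callable[[], float],
) -> SimulationState:
    """Advance the contagion by one step (mutates and returns ``state``).

    Spreaders are all nodes infected before this step, visited in shuffled
    order; each spreader's susceptible neighbours are shuffled too.  A node
    infected earlier within the step is excluded from later spreaders'
    neighbour lists (no draw is consumed for it).  Failed contacts habituate
    the target immediately when habituation is enabled.
    """
    adj = state.adj
    infected = state.infected
    y = state.y
    c = state.c
    phase = state.phase
    params = cfg.hab_params
    y0 = params.y0
    s_over_a = params.S / params.alpha
    a_over_t = params.alpha / params.tau
    exp = math.exp
    pp = cfg.pp
    hab = cfg.habituation_enabled
    strict = cfg.strict_inequality
    recovery = cfg.recovery_enabled
    shuffle = shuffle_rng.shuffle

    spreaders = list(state.infected_order)
    shuffle(spreaders)
    contacts = 0
    failures = 0
    new: list = []
    contacted = [False] * len(infected) if recovery else None
    sum_y_all = state.sum_y_all

    for u in spreaders:
        cands = [v for v in adj[u] if not infected[v]]
        if not cands:
            continue
        shuffle(cands)
        for v in cands:
            x = uniform()
            contacts += 1
            if contacted is not None:
                contacted[v] = True
            thr = pp * y[v] if hab else pp
            hit = (x < thr) if strict else (x <= thr)
            if hit:
                infected[v] = True
                new.append(v)
                state.infected_order.append(v)
                state.sum_y_infected += y[v]
            else:
                failures += 1
                if hab:
                    cv = c[v] + 1
                    c[v] = cv
                    phase[v] = _PH_DECREASING
                    state.rec_elapsed[v] = 0
                    ynew = y0 - s_over_a * (1.0 - exp(-a_over_t * cv))
                    sum_y_all += ynew - y[v]
                    y[v] = ynew

    if recovery and hab:
        y1 = state.y1
        rec = state.rec_elapsed
        assert contacted is not None
        for v in range(len(infected)):
            if infected[v] or contacted[v] or phase[v] == _PH_BASELINE:
                continue
            if phase[v] == _PH_DECREASING:
                phase[v] = _PH_RECOVERING
                y1[v] = y[v]
                rec[v] = 1
            else:
                rec[v] += 1
                ynew = y0 - (y0 - y1[v]) * exp(-a_over_t * (rec[v] - 1))
                sum_y_all += ynew - y[v]
                y[v] = ynew

    state.sum_y_all = sum_y_all
    state.newly_infected = new
    state.contacts_last_step = contacts
    state.failures_last_step = failures
    state.step_index += 1
    return state


def mean_responsiveness(state: SimulationState, partition: str) -> float | None:
    """Arithmetic mean responsiveness over ``all``/``infected``/``uninfected``.

    Infected nodes contribute the responsiveness they had when infected
    (frozen).  Returns None for an empty partition.  Recomputed from scratch;
    the run loop keeps equivalent incremental sums.
    """
    if partition == "all":
        vals = state.y
    elif partition == "infected":
        vals = [state.y[v] for v in state.infected_order]
    elif partition == "uninfected":
        vals = [yv for yv, inf in zip(state.y, state.infected) if not inf]
    else:
        raise ValueError(f"unknown partition {partition!r}")
    if not vals:
        return None
    return sum(vals) / len(vals)


@dataclass
class Trajectory:
    """Per-step record of one run.

    Index 0 is the seeding step (zero contacts); entry s describes the state
    after step s.  Mean-responsiveness series are None where the partition is
    empty.  ``draws`` holds the consumed per-contact uniforms when recording
    was requested.
    """

    coverage_by_step: list
    contacts_by_step: list
    failed_contacts_by_step: list
    mean_responsiveness_all: list
    mean_responsiveness_infected: list
    mean_responsiveness_uninfected: list
    stop_reason: str
    n_nodes: int
    config: SimulationConfig
    draws: list | None = None

    @property
    def n_steps(self) -> int:
        """Number of contagion steps executed (excludes the seeding step)."""
        return len(self.coverage_by_step) - 1

    def coverage_at(self, step: int) -> float:
        """Coverage after ``step`` steps; a finished run holds its final value."""
        return self.coverage_by_step[min(step, len(self.coverage_by_step) - 1)]

    def duration_to(self, threshold: float) -> int | None:
        return duration_to_coverage(self, threshold)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.coverage_by_step)),
                "coverage": self.coverage_by_step,
                "contacts": self.contacts_by_step,
                "failed_contacts": self.failed_contacts_by_step,
                "mean_resp_all": self.mean_responsiveness_all,
                "mean_resp_infected": self.mean_responsiveness_infected,
                "mean_resp_uninfected": self.mean_responsiveness_uninfected,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def duration_to_coverage(traj: Trajectory, threshold: float) -> int | None:
    """Smallest step with coverage >= threshold, or None if never reached."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    for s, cov in enumerate(traj.coverage_by_step):
        if cov >= threshold:
            return s
    return None


class _Recorder:
    """Wraps a uniform source, keeping every value it hands out."""

    def __init__(self, inner: Callable[[], float]):
        self.inner = inner
        self.values: list = []

    def __call__(self) -> float:
        x = self.inner()
        self.values.append(x)
        return x


def run(
    g: nx.Graph,
    cfg: SimulationConfig,
    draws: Callable[[], float] | None = None,
    record_draws: bool = False,
) -> Trajectory:
    """Execute a full SI run and return its trajectory.

    ``draws``, when given, replaces the per-contact uniform stream (one call
    per contact) — shuffles still come from the seed-derived shuffle stream,
    which is what makes scripted replays bit-compatible with live runs.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot simulate on an empty graph")
    state = initialize_state(g, cfg)
    shuffle_rng = _stream("shuffle", cfg.rng_seed)
    uniform: Callable[[], float] = draws if draws is not None else _stream("draws", cfg.rng_seed).random
    recorder = None
    if record_draws:
        recorder = _Recorder(uniform)
        uniform = recorder

    coverage = [state.coverage]
    contacts = [0]
    failed = [0]
    resp_all = [mean_responsiveness(state, "all")]
    resp_inf = [mean_responsiveness(state, "infected")]
    resp_uninf = [mean_responsiveness(state, "uninfected")]

    while True:
        if state.coverage >= cfg.coverage_target:
            stop = TARGET_REACHED
            break
        if state.step_index >= cfg.max_steps:
            stop = MAX_STEPS
            break
        run_step(state, cfg, shuffle_rng, uniform)
        n = state.n_nodes
        n_inf = state.n_infected
        coverage.append(n_inf / n)
        contacts.append(state.contacts_last_step)
        failed.append(state.failures_last_step)
        resp_all.append(state.sum_y_all / n)
        resp_inf.append(state.sum_y_infected / n_inf if n_inf else None)
        resp_uninf.append(
            (state.sum_y_all - state.sum_y_infected) / (n - n_inf) if n > n_inf else None
        )

    return Trajectory(
        coverage_by_step=coverage,
        contacts_by_step=contacts,
        failed_contacts_by_step=failed,
        mean_responsiveness_all=resp_all,
        mean_responsiveness_infected=resp_inf,
        mean_responsiveness_uninfected=resp_uninf,
        stop_reason=stop,
        n_nodes=state.n_nodes,
        config=cfg,
        draws=recorder.values if recorder is not None else None,
    )
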