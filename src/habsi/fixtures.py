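"""Deterministic fixtures: a toy network, scripted draws, stand-in networks.

Everything here exists so the whole pipeline is testable without external
downloads: a seven-node toy graph mirroring the documented worked trace, a
scripted-draw replayer that substitutes explicit uniforms for the RNG, and
four synthetic stand-ins approximating the size and mean degree of the four
real study networks.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import networkx as nx

from .network import generate_graph, read_edge_list
from .simulate import SimulationConfig, Trajectory, run
from .util import derive_seed

__all__ = [
    "DrawsExhaustedError",
    "ScriptedDraws",
    "build_toy_graph",
    "replay",
    "make_stand_in_networks",
    "STAND_IN_SPECS",
]


class DrawsExhaustedError(RuntimeError):
    """The scripted draw sequence ran out before the run finished.

    Raised instead of silently recycling values, so any drift in the
    simulator's draw order is caught immediately.
    """


class ScriptedDraws:
    """A fixed sequence of uniforms consumed one value per contact.

    Contacts happen in the simulator's shuffled order (spreaders, then each
    spreader's susceptible neighbours); with a single spreader and a single
    susceptible neighbour the order is trivially deterministic, which is how
    the worked-trace fixtures use it.
    """

    def __init__(self, values) -> None:
        vals = [float(v) for v in values]
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"scripted draw {v!r} outside [0, 1]")
        self._values = vals
        self._pos = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "ScriptedDraws":
        """Load one-value-per-line plain text (``#`` comments allowed)."""
        values = []
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if line:
                values.append(float(line))
        return cls(values)

    @classmethod
    def toy(cls) -> "ScriptedDraws":
        """The bundled three-contact sequence: fail, fail, succeed at 0.06."""
        ref = resources.files("habsi").joinpath("data/toy_draws.txt")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    @property
    def remaining(self) -> int:
        return len(self._values) - self._pos

    def __len__(self) -> int:
        return len(self._values)

    def __call__(self) -> float:
        if self._pos >= len(self._values):
            raise DrawsExhaustedError(
                f"scripted draws exhausted after {len(self._values)} contacts"
            )
        v = self._values[self._pos]
        self._pos += 1
        return v


def build_toy_graph() -> nx.Graph:
    """The bundled seven-node, eight-edge toy network.

    An approximation of the worked-trace slice, not a reproduction: the trace
    names only four of its ties (1-3, 1-4, 2-4, 4-6), so the other four are
    fixed, documented fillers.
    """
    ref = resources.files("habsi").joinpath("data/toy_7node_synthetic.edges")
    with resources.as_file(ref) as path:
        g = read_edge_list(path)
    g.graph["name"] = "toy"
    return g


def replay(g: nx.Graph, cfg: SimulationConfig, draws: ScriptedDraws) -> Trajectory:
    """Run the simulator with injected per-contact uniforms.

    Identical semantics to :func:`habsi.simulate.run`; shuffles still come
    from the config's seed-derived stream, so replaying the uniforms recorded
    from a live run (same config) reproduces it exactly.
    """
    return run(g, cfg, draws=draws)


#: (name, n, m) of the Barabasi-Albert stand-ins; n and the resulting mean
#: degree (~2m(n-m)/n) approximate the four real study networks.
STAND_IN_SPECS = (
    ("SN1", 899, 8),
    ("SN2", 1224, 14),
    ("SN3", 1858, 7),
    ("SN4", 1899, 7),
)


def make_stand_in_networks(rng_seed: int) -> list[nx.Graph]:
    """Four seed-deterministic synthetic stand-ins for the study networks.

    Barabasi-Albert topology (heavy-tailed degree, social-network-like) with
    (n, mean degree) ~ (899, 15.9), (1224, 27.7), (1858, 13.9), (1899, 13.9).
    Clustering / centrality / modularity of the real networks are not matched.
    """
    graphs = []
    for i, (name, n, m) in enumerate(STAND_IN_SPECS):
        g = generate_graph("barabasi_albert", rng_seed=derive_seed("standin", rng_seed, i), n=n, m=m)
        g.graph["name"] = name
        graphs.append(g)
    return graphs
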