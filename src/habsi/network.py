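"""Graph ingestion, synthetic graph generation, and descriptive metrics.

The contact process is symmetric and per-edge, so every graph is coerced to a
simple undirected :class:`networkx.Graph` with string node labels.  Node
identifiers are opaque; the simulator maps them to dense indices internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

__all__ = [
    "GraphFormatError",
    "EmptyGraphError",
    "NetworkMetrics",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "generate_graph",
    "compute_metrics",
]

logger = logging.getLogger(__name__)


class GraphFormatError(ValueError):
    """Malformed or unsupported graph input."""


class EmptyGraphError(GraphFormatError):
    """Graph source contains no edges or nodes."""


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a whitespace-separated edge list into a simple undirected graph.

    One edge per line, two tokens; ``#`` starts a comment.  Duplicate edges
    are collapsed and self-loops dropped with a warning.  Node identifiers are
    preserved verbatim (as strings).
    """
    path = Path(path)
    g = nx.Graph(name=path.stem)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two whitespace-separated node "
                    f"tokens, got {len(tokens)}: {raw.rstrip()!r}"
                )
            u, v = tokens
            if u == v:
                logger.warning("%s:%d: dropping self-loop on node %r", path, lineno, u)
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError(f"{path}: no edges found")
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write a canonical (sorted, deduplicated) edge list; round-trip stable."""
    path = Path(path)
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in g.edges())
    with path.open("w") as fh:
        for u, v in edges:
            fh.write(f"{u} {v}\n")


def read_graphml(path: str | Path) -> nx.Graph:
    """Read an undirected GraphML file; directed graphs are rejected."""
    loaded = nx.read_graphml(path)
    if loaded.is_directed():
        raise GraphFormatError(f"{path}: directed GraphML is not supported; the contact model is undirected")
    g = nx.Graph(name=Path(path).stem)
    g.add_nodes_from(str(n) for n in loaded.nodes())
    g.add_edges_from(
        (str(u), str(v)) for u, v in loaded.edges() if str(u) != str(v)
    )
    return g


_MODELS = ("erdos_renyi", "barabasi_albert", "watts_strogatz")


def generate_graph(model: str, rng_seed: int = 0, **params) -> nx.Graph:
    """Generate a seed-deterministic synthetic graph.

    Supported models and their parameters:

    - ``erdos_renyi``: ``n`` nodes, edge probability ``p``.
    - ``barabasi_albert``: ``n`` nodes, ``m`` edges per new node
      (mean degree ~ 2m; heavy-tailed, social-network-like).
    - ``watts_strogatz``: ``n`` nodes, ``k`` ring neighbours, rewiring ``p``.

    Node labels are stringified; the result is simple and undirected.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose one of {_MODELS}")
    n = params.get("n")
    if n is None or n < 2:
        raise ValueError(f"model {model!r} requires n >= 2 nodes, got {n!r}")
    if model == "erdos_renyi":
        p = params.get("p")
        if p is None or not 0 <= p <= 1:
            raise ValueError(f"erdos_renyi requires 0 <= p <= 1, got {p!r}")
        g = nx.gnp_random_graph(n, p, seed=rng_seed)
    elif model == "barabasi_albert":
        m = params.get("m")
        if m is None or not 1 <= m < n:
            raise ValueError(f"barabasi_albert requires 1 <= m < n, got {m!r}")
        g = nx.barabasi_albert_graph(n, m, seed=rng_seed)
    else:
        k = params.get("k")
        p = params.get("p")
        if k is None or not 2 <= k < n:
            raise ValueError(f"watts_strogatz requires 2 <= k < n, got {k!r}")
        if p is None or not 0 <= p <= 1:
            raise ValueError(f"watts_strogatz requires 0 <= p <= 1, got {p!r}")
        g = nx.watts_strogatz_graph(n, k, p, seed=rng_seed)
    g = nx.relabel_nodes(g, {i: str(i) for i in g.nodes()})
    g.graph["name"] = f"{model}:{rng_seed}"
    return g


@dataclass(frozen=True)
class NetworkMetrics:
    """Descriptive statistics of a contact network.

    ``mean_degree`` (DG), ``density`` (ND), ``global_clustering`` (CC,
    transitivity), ``mean_eigenvector`` (EV) and ``modularity`` (MD, from a
    greedy modularity-maximising partition — a heuristic, so exact agreement
    with other tools' MD values is not expected).
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    density: float
    global_clustering: float
    mean_eigenvector: float
    modularity: float


def compute_metrics(g: nx.Graph) -> NetworkMetrics:
    """Compute the descriptive metrics of a non-empty simple graph.

    Eigenvector centrality is evaluated on the largest connected component
    when the graph is disconnected (with a logged note), since the power
    iteration is undefined across components.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyGraphError("cannot compute metrics of an empty graph")
    e = g.number_of_edges()
    if nx.is_connected(g):
        ev_graph = g
    else:
        comp = max(nx.connected_components(g), key=len)
        ev_graph = g.subgraph(comp)
        logger.info(
            "graph is disconnected; eigenvector centrality computed on the "
            "largest component (%d of %d nodes)", len(comp), n,
        )
    if ev_graph.number_of_edges() == 0:
        mean_ev = 0.0
    else:
        centrality = nx.eigenvector_centrality_numpy(ev_graph)
        mean_ev = sum(centrality.values()) / len(centrality)
    communities = nx.community.greedy_modularity_communities(g)
    md = nx.community.modularity(g, communities) if e > 0 else 0.0
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        mean_degree=2 * e / n,
        density=nx.density(g),
        global_clustering=nx.transitivity(g),
        mean_eigenvector=mean_ev,
        modularity=md,
    )
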