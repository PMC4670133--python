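"""Co-activation network construction and metrics.

Two responding cells are linked when they activated within
``co_activation_window`` seconds of each other (|t_res,i - t_res,j| <= 1 s
by default, boundary inclusive) and lie strictly closer than
``distance_cutoff`` (30 um) — the spatial constraint removes spurious
links between remote cells that merely happened to respond together.
The resulting undirected, unweighted graph is characterized by the
average degree k_avg, the Watts-Strogatz average clustering coefficient
C_avg, the global efficiency E_G, and the relative number of Louvain
communities n_c / N (segregation), with the community count averaged
over seeded restarts because the algorithm is order-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from networkx.algorithms.community import louvain_communities, modularity

__all__ = [
    "NetworkMetrics",
    "build_network",
    "average_degree",
    "clustering_coefficient",
    "global_efficiency",
    "detect_communities",
    "network_metrics",
]


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    k_avg: float
    c_avg: float
    e_glob: float
    n_communities: float      # mean over Louvain restarts
    n_c_over_n: float
    modularity_q: float       # mean over restarts
    n_louvain_runs: int


def build_network(t_res: np.ndarray, positions: np.ndarray,
                  responder_mask: np.ndarray | None = None,
                  co_activation_window: float = 1.0,
                  distance_cutoff: float = 30.0) -> nx.Graph:
    """Activation network over responding cells.

    Nodes are the indices of responders (non-responders carry no t_res
    and are excluded); an edge requires both the temporal window
    (inclusive) and the spatial cutoff (strict).  Node attributes ``x``,
    ``y`` and ``t_res`` are set for export/rendering.
    """
    t_res = np.asarray(t_res, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if responder_mask is None:
        responder_mask = np.isfinite(t_res)
    idx = np.nonzero(np.asarray(responder_mask, dtype=bool)
                     & np.isfinite(t_res))[0]
    g = nx.Graph()
    for i in idx:
        g.add_node(int(i), x=float(positions[i, 0]), y=float(positions[i, 1]),
                   t_res=float(t_res[i]))
    for a in range(idx.size):
        i = idx[a]
        for b in range(a + 1, idx.size):
            j = idx[b]
            if abs(t_res[i] - t_res[j]) <= co_activation_window and \
                    float(np.linalg.norm(positions[i] - positions[j])) < distance_cutoff:
                g.add_edge(int(i), int(j))
    return g


def average_degree(g: nx.Graph) -> float:
    """k_avg = 2|E| / N."""
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    return 2.0 * g.number_of_edges() / n


def clustering_coefficient(g: nx.Graph) -> float:
    """Mean local clustering C_i = 2 n_i / (k_i (k_i - 1)); C_i = 0 for k_i < 2."""
    if g.number_of_nodes() < 1:
        raise ValueError("empty graph")
    return float(nx.average_clustering(g))


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered pairs; 1/inf = 0."""
    if g.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    return float(nx.global_efficiency(g))


def detect_communities(g: nx.Graph, runs: int = 20,
                       seed: int = 0) -> tuple[float, float, float]:
    """Louvain modularity maximization, averaged over seeded restarts.

    Returns ``(n_c, q, n_c_over_n)`` where n_c is the mean community
    count (isolated nodes are singleton communities) and q the mean
    modularity of the best partition per run.
    """
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        return float(n), 0.0, 1.0
    rng = np.random.default_rng(seed)
    counts, qs = [], []
    for _ in range(runs):
        run_seed = int(rng.integers(0, 2 ** 31 - 1))
        parts = louvain_communities(g, seed=run_seed)
        counts.append(len(parts))
        qs.append(modularity(g, parts))
    n_c = float(np.mean(counts))
    return n_c, float(np.mean(qs)), n_c / n


def network_metrics(g: nx.Graph, runs: int = 20, seed: int = 0) -> NetworkMetrics:
    """k_avg, C_avg, E_G and community structure of one activation network."""
    n = g.number_of_nodes()
    n_c, q, ratio = detect_communities(g, runs=runs, seed=seed)
    return NetworkMetrics(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        k_avg=average_degree(g),
        c_avg=clustering_coefficient(g),
        e_glob=global_efficiency(g) if n >= 2 else 0.0,
        n_communities=n_c,
        n_c_over_n=ratio,
        modularity_q=q,
        n_louvain_runs=runs,
    )
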