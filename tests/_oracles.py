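"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible (explicit loops,
textbook formulas) so it cannot share a bug with the vectorized package
code it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def pearson_brute(a, b) -> float:
    """Textbook Pearson correlation via explicit sums."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return num / math.sqrt(va * vb)


def delta_tau_brute(times, positions, bin_edges):
    """Eq-style grouping statistic via an explicit double loop.

    Returns {(lo, hi): value} for non-empty bins: for each cell i, the
    mean |tau_i - tau_j| over cells j whose distance from i falls in the
    bin, averaged over cells with at least one such neighbor.
    """
    n = len(times)
    out = {}
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        per_cell = []
        for i in range(n):
            diffs = []
            for j in range(n):
                if i == j:
                    continue
                d = math.dist(positions[i], positions[j])
                if lo <= d < hi:
                    diffs.append(abs(times[i] - times[j]))
            if diffs:
                per_cell.append(sum(diffs) / len(diffs))
        if per_cell:
            out[(lo, hi)] = sum(per_cell) / len(per_cell)
    return out


def degree_brute(g: nx.Graph) -> float:
    degs = [sum(1 for _ in g.neighbors(v)) for v in g]
    return sum(degs) / len(degs)


def clustering_brute(g: nx.Graph) -> float:
    """Watts-Strogatz average clustering by explicit triangle counting."""
    cs = []
    for v in g:
        nb = list(g.neighbors(v))
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2)
                    if g.has_edge(a, b))
        cs.append(2.0 * links / (k * (k - 1)))
    return sum(cs) / len(cs)


def efficiency_brute(g: nx.Graph) -> float:
    """Global efficiency via per-source BFS; disconnected pairs give 0."""
    nodes = list(g)
    n = len(nodes)
    total = 0.0
    for s in nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t in nodes:
            if t != s and t in dist:
                total += 1.0 / dist[t]
    return total / (n * (n - 1))


def _set_partitions(items):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield part + [[first]]


def best_modularity_brute(g: nx.Graph):
    """Exhaustive modularity maximization (feasible for N <= 8).

    Returns (best_q, best_partition_as_sets).
    """
    nodes = list(g)
    best_q, best_p = -math.inf, None
    for part in _set_partitions(nodes):
        q = nx.community.modularity(g, [set(b) for b in part])
        if q > best_q:
            best_q, best_p = q, [set(b) for b in part]
    return best_q, best_p


def anova_f_brute(groups):
    """One-way ANOVA F via explicit sum-of-squares decomposition."""
    all_vals = [x for g in groups for x in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    return (ss_between / (k - 1)) / (ss_within / (n - k))
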