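"""Shared test utilities: dataset builders and brute-force graph oracles.

The oracles here are deliberately independent of the package implementation:
distances and betweenness are computed by exhaustive enumeration of simple
paths, and quantile assignment by explicit rank counting.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from sbnet.dataset import CategoricalDataset
from sbnet.schema import VariableSchema


def make_dataset(columns: dict[str, np.ndarray], cluster: str = "demographic",
                 cards: dict[str, int] | None = None) -> CategoricalDataset:
    """Build a CategoricalDataset from integer code arrays."""
    schema = []
    mats = []
    for name, codes in columns.items():
        codes = np.asarray(codes, dtype=np.int64)
        k = cards[name] if cards and name in cards else int(codes.max(initial=0)) + 1
        k = max(k, 2)
        schema.append(
            VariableSchema(name, cluster, tuple(f"l{i}" for i in range(k)))
        )
        mats.append(codes)
    return CategoricalDataset(schema, np.column_stack(mats))


# --------------------------------------------------------------------------- #
# brute-force graph oracles
# --------------------------------------------------------------------------- #

def all_simple_paths(graph: nx.Graph, s, t):
    """Exhaustive simple-path enumeration by DFS (independent of networkx)."""
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for nxt in sorted(graph.neighbors(last)):
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([s])
    return paths


def bruteforce_distances(graph: nx.Graph, target) -> dict:
    """Hop distance to target via enumeration of all simple paths."""
    out = {}
    for node in graph.nodes:
        if node == target:
            out[node] = 0
            continue
        paths = all_simple_paths(graph, node, target)
        out[node] = min((len(p) - 1 for p in paths), default=None)
    return out


def bruteforce_weighted_betweenness(
    graph: nx.Graph, weight: str = "cost", normalized: bool = True
) -> dict:
    """Betweenness from exhaustive weighted shortest-path enumeration.

    For every unordered pair (s, t) the minimum-cost simple paths are found by
    enumeration; each intermediate node v accrues sigma_st(v)/sigma_st.
    """
    nodes = sorted(graph.nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(graph, s, t)
        if not paths:
            continue
        costs = [
            sum(graph[u][v][weight] for u, v in zip(p, p[1:])) for p in paths
        ]
        best = min(costs)
        shortest = [p for p, c in zip(paths, costs) if c == best]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    if normalized and len(nodes) > 2:
        scale = 2.0 / ((len(nodes) - 1) * (len(nodes) - 2))
        bc = {v: val * scale for v, val in bc.items()}
    return bc


def random_strength_graph(rng: np.random.Generator, max_nodes: int = 7) -> nx.Graph:
    """Random connected-ish undirected graph with integer-cost strengths.

    Strengths are 1/w for small integer w, so edge costs (1/strength) are
    exact small integers and float shortest-path comparisons are exact.
    """
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                w = int(rng.integers(1, 9))
                g.add_edge(f"n{i}", f"n{j}", strength=1.0 / w, cost=float(w))
    return g


def structural_hamming_distance(edges_a: set[frozenset], edges_b: set[frozenset]) -> int:
    return len(edges_a ^ edges_b)
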