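"""Discrete Bayesian-network structure learning from scratch.

Implements the G-squared conditional-independence test, the decomposable BIC
network score, a PC-style (order-invariant) skeleton learner and a restricted
greedy hill-climbing search.  Together these form the hybrid
restrict-then-maximise algorithm used throughout the pipeline.

All counting is done with ``numpy.bincount`` over mixed-radix cell codes, so a
single test or local score costs O(n) with small constants.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.special import chdtrc  # chi-square upper tail, fast scalar path

from .dataset import CategoricalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CITestResult",
    "StructureConfig",
    "contingency_counts",
    "g2_test",
    "bic_score",
    "local_bic",
    "learn_skeleton",
    "hill_climb",
    "learn_structure",
]


@dataclasses.dataclass(frozen=True)
class CITestResult:
    """Outcome of a conditional-independence test."""

    statistic: float
    dof: int
    p_value: float

    @property
    def informative(self) -> bool:
        return self.dof > 0


@dataclasses.dataclass
class StructureConfig:
    """Knobs for the hybrid learner."""

    alpha: float = 0.05
    max_sepset: int = 2
    score: str = "bic"
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_sepset < 0:
            raise ValueError("max_sepset must be >= 0")


# --------------------------------------------------------------------------- #
# contingency counting and the G^2 test
# --------------------------------------------------------------------------- #

def _mixed_radix(columns: Sequence[np.ndarray], cards: Sequence[int]) -> np.ndarray:
    """Combine code columns into a single cell index (row-major)."""
    if not columns:
        return np.zeros(0, dtype=np.int64)
    code = columns[0].astype(np.int64)
    for col, k in zip(columns[1:], cards[1:]):
        code = code * k + col
    return code


def contingency_counts(
    data: CategoricalDataset, x: str, y: str, z: Iterable[str] = ()
) -> np.ndarray:
    """Counts over levels(x) x levels(y) x z-configurations.

    Returns an array of shape ``(kx, ky, prod(kz))``; zero cells are kept.
    """
    z = list(z)
    roles = [x, y, *z]
    if len(set(roles)) != len(roles):
        raise ValueError(f"variables must be distinct, got x={x!r} y={y!r} z={z!r}")
    kx, ky = data.cardinality(x), data.cardinality(y)
    kz = int(np.prod([data.cardinality(v) for v in z], dtype=np.int64)) if z else 1
    zc = _mixed_radix([data.column(v) for v in z], [data.cardinality(v) for v in z]) \
        if z else np.zeros(data.n_rows, dtype=np.int64)
    code = (zc * kx + data.column(x)) * ky + data.column(y)
    counts = np.bincount(code, minlength=kx * ky * kz)
    return counts.reshape(kz, kx, ky).transpose(1, 2, 0)


def _g2_from_counts(counts: np.ndarray) -> CITestResult:
    """G^2 statistic from a (kx, ky, nz) count array.

    Degrees of freedom use the standard sparse adjustment: within each
    z-configuration, rows and columns with zero marginals do not contribute.
    """
    return _g2_from_slices(np.ascontiguousarray(counts.transpose(2, 0, 1)))


def _g2_from_slices(tab: np.ndarray) -> CITestResult:
    """G^2 from counts shaped (nz, kx, ky), vectorised across z-slices.

    Slices where one margin has a single observed level contribute 0 to both
    the statistic (expected == observed there) and the degrees of freedom.
    """
    rows = np.add.reduce(tab, axis=2)  # (nz, kx)
    cols = np.add.reduce(tab, axis=1)  # (nz, ky)
    tot = np.add.reduce(rows, axis=1)  # (nz,)
    nr = np.add.reduce(rows > 0, axis=1)
    nc = np.add.reduce(cols > 0, axis=1)
    dof = int(np.add.reduce(np.maximum(nr - 1, 0) * np.maximum(nc - 1, 0)))
    if dof == 0:
        return CITestResult(0.0, 0, 1.0)
    safe_tot = np.where(tot > 0, tot, 1).astype(float)
    expected = rows[:, :, None] * (cols[:, None, :] / safe_tot[:, None, None])
    ratio = np.divide(
        tab, expected, out=np.ones_like(expected, dtype=float), where=tab > 0
    )
    stat = 2.0 * float(np.add.reduce((tab * np.log(ratio)).ravel()))
    stat = max(stat, 0.0)
    return CITestResult(stat, dof, float(chdtrc(dof, stat)))


def g2_test(
    data: CategoricalDataset, x: str, y: str, z: Iterable[str] = ()
) -> CITestResult:
    """Likelihood-ratio test of x independent of y given z.

    G^2 = 2 sum O ln(O/E) within each z-configuration; the p-value comes from
    the chi-square upper tail.  A variable observed at a single level yields an
    uninformative result (dof 0, p 1) rather than a spurious significance.
    """
    if x == y:
        raise ValueError("x and y must differ")
    return _g2_from_counts(contingency_counts(data, x, y, z))


# --------------------------------------------------------------------------- #
# BIC score
# --------------------------------------------------------------------------- #

def local_bic(data: CategoricalDataset, node: str, parents: Sequence[str]) -> float:
    """BIC contribution of one node given its parents.

    Multinomial log-likelihood minus (ln n)/2 times the number of free
    parameters, counting the full cross-product of parent configurations.
    """
    n = data.n_rows
    k = data.cardinality(node)
    parents = list(parents)
    q = int(np.prod([data.cardinality(p) for p in parents], dtype=np.int64)) if parents else 1
    cfg = _mixed_radix([data.column(p) for p in parents],
                       [data.cardinality(p) for p in parents]) \
        if parents else np.zeros(n, dtype=np.int64)
    code = cfg * k + data.column(node)
    counts = np.bincount(code, minlength=q * k).reshape(q, k)
    row_tot = counts.sum(axis=1, keepdims=True)
    nz = counts > 0
    ll = float(np.sum(counts[nz] * np.log(counts[nz] / np.broadcast_to(row_tot, counts.shape)[nz])))
    penalty = 0.5 * np.log(n) * (k - 1) * q if n > 0 else 0.0
    return ll - penalty


def bic_score(
    data: CategoricalDataset, graph: nx.DiGraph
) -> tuple[float, dict[str, float]]:
    """Decomposed BIC of a DAG; returns (total, per-node terms)."""
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("graph must be acyclic")
    unknown = [v for v in graph.nodes if v not in data]
    if unknown:
        raise KeyError(f"graph nodes not in data: {unknown}")
    per_node = {
        node: local_bic(data, node, sorted(graph.predecessors(node)))
        for node in graph.nodes
    }
    return float(sum(per_node.values())), per_node


# --------------------------------------------------------------------------- #
# skeleton learning (restrict phase)
# --------------------------------------------------------------------------- #

class _FastTester:
    """G^2 testing against cached per-variable code columns.

    Caches the combined code of each conditioning set so repeated tests with
    the same set across many pairs cost two vector ops plus one bincount.

    A row-multiplicity weight vector emulates a with-replacement resample of
    the data without materialising it, which lets one tester (and its code
    caches) be shared across all bootstrap replicates.
    """

    def __init__(self, data: CategoricalDataset, weights: np.ndarray | None = None):
        self.cards = {v.name: v.cardinality for v in data.schema}
        self.cols = {v.name: data.column(v.name).astype(np.int64) for v in data.schema}
        self.n = data.n_rows
        self.weights: np.ndarray | None = None
        if weights is not None:
            self.set_weights(weights)
        self._zcache: dict[tuple[str, ...], tuple[np.ndarray, int]] = {}

    def set_weights(self, weights: np.ndarray | None) -> None:
        if weights is None:
            self.weights = None
            return
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (self.n,):
            raise ValueError(f"weights must have shape ({self.n},)")
        self.weights = weights

    @property
    def total(self) -> float:
        return float(self.weights.sum()) if self.weights is not None else float(self.n)

    def _bincount(self, code: np.ndarray, minlength: int) -> np.ndarray:
        if self.weights is None:
            return np.bincount(code, minlength=minlength)
        return np.bincount(code, weights=self.weights, minlength=minlength)

    def _zcode(self, z: tuple[str, ...]) -> tuple[np.ndarray, int]:
        if not z:
            return np.zeros(self.n, dtype=np.int64), 1
        hit = self._zcache.get(z)
        if hit is not None:
            return hit
        code = self.cols[z[0]]
        kz = self.cards[z[0]]
        for v in z[1:]:
            code = code * self.cards[v] + self.cols[v]
            kz *= self.cards[v]
        result = (code, kz)
        if len(z) > 1:
            self._zcache[z] = result
        return result

    def pair_code(self, x: str, y: str) -> tuple[np.ndarray, int, int]:
        kx, ky = self.cards[x], self.cards[y]
        return self.cols[x] * ky + self.cols[y], kx, ky

    def test(self, x: str, y: str, z: tuple[str, ...]) -> CITestResult:
        return self.test_pair(*self.pair_code(x, y), z)

    def test_pair(
        self, xy: np.ndarray, kx: int, ky: int, z: tuple[str, ...]
    ) -> CITestResult:
        zc, kz = self._zcode(z)
        if kz == 1:
            counts = self._bincount(xy, kx * ky)
        else:
            code = zc * (kx * ky)
            code += xy
            counts = self._bincount(code, kx * ky * kz)
        return _g2_from_slices(counts.reshape(kz, kx, ky))

    def family_counts(self, node: str, parents: tuple[str, ...]) -> np.ndarray:
        """Counts of (parent configuration, node level), shape (q, k)."""
        k = self.cards[node]
        zc, q = self._zcode(parents)
        if q == 1:
            counts = self._bincount(self.cols[node], k)
        else:
            counts = self._bincount(zc * k + self.cols[node], q * k)
        return counts.reshape(q, k)

    def local_bic(self, node: str, parents: tuple[str, ...]) -> float:
        counts = self.family_counts(node, parents)
        row_tot = counts.sum(axis=1, keepdims=True)
        nz = counts > 0
        obs = counts[nz].astype(float)
        ll = float(np.sum(obs * np.log(obs / np.broadcast_to(row_tot, counts.shape)[nz])))
        n = self.total
        penalty = 0.5 * np.log(n) * (self.cards[node] - 1) * counts.shape[0] if n > 0 else 0.0
        return ll - penalty


def learn_skeleton(
    data: CategoricalDataset,
    alpha: float = 0.05,
    max_sepset: int = 2,
    tester: _FastTester | None = None,
) -> nx.Graph:
    """PC-stable skeleton: drop edge x-y iff some conditioning set of size up
    to ``max_sepset`` drawn from current neighbourhoods renders them
    independent at ``alpha``.

    Adjacency sets are snapshotted per level and pairs visited in
    lexicographic order, so the result does not depend on input variable
    order.
    """
    if data.n_rows == 0:
        raise ValueError("cannot learn a skeleton from an empty dataset")
    nodes = sorted(data.columns)
    if tester is None:
        tester = _FastTester(data)
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    # marginal association strengths recorded at level 0; used to try the most
    # strongly associated candidates first at higher levels (separating sets
    # are usually found early, cutting the number of tests substantially)
    assoc: dict[frozenset, float] = {}

    for level in range(0, max_sepset + 1):
        snapshot = {v: sorted(adj[v]) for v in nodes}
        if all(len(snapshot[v]) - 1 < level for v in nodes):
            break
        to_remove: list[tuple[str, str]] = []
        for x in nodes:
            for y in snapshot[x]:
                if y <= x or y not in adj[x]:
                    continue
                separated = False
                seen: set[tuple[str, ...]] = set()
                xy, kx, ky = tester.pair_code(x, y)
                if level == 0:
                    res = tester.test_pair(xy, kx, ky, ())
                    assoc[frozenset((x, y))] = res.statistic / max(res.dof, 1)
                    if not res.informative or res.p_value > alpha:
                        separated = True
                else:
                    def rank(v: str) -> tuple[float, str]:
                        s = max(
                            assoc.get(frozenset((v, x)), 0.0),
                            assoc.get(frozenset((v, y)), 0.0),
                        )
                        return (-s, v)

                    for base in (snapshot[x], snapshot[y]):
                        cands = sorted(
                            (v for v in base if v != x and v != y), key=rank
                        )
                        if len(cands) < level:
                            continue
                        for sub in itertools.combinations(cands, level):
                            if sub in seen:
                                continue
                            seen.add(sub)
                            res = tester.test_pair(xy, kx, ky, tuple(sorted(sub)))
                            if res.informative and res.p_value > alpha:
                                separated = True
                                break
                        if separated:
                            break
                if separated:
                    to_remove.append((x, y))
        for x, y in to_remove:
            adj[x].discard(y)
            adj[y].discard(x)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for x in nodes:
        for y in adj[x]:
            if x < y:
                g.add_edge(x, y)
    return g


# --------------------------------------------------------------------------- #
# hill climbing (maximise phase)
# --------------------------------------------------------------------------- #

def _would_cycle(graph: nx.DiGraph, u: str, v: str) -> bool:
    """Would adding arc u->v create a cycle?"""
    return graph.has_edge(v, u) or nx.has_path(graph, v, u)


def hill_climb(
    data: CategoricalDataset,
    restrict: nx.Graph,
    score: str | Callable[[CategoricalDataset, str, Sequence[str]], float] = "bic",
    max_iter: int = 1000,
    seed: int = 0,
    tester: _FastTester | None = None,
    trace: list | None = None,
) -> nx.DiGraph:
    """Greedy arc addition/deletion/reversal restricted to a skeleton.

    When ``trace`` is a list, the total score after every accepted move is
    appended to it (strictly increasing by construction).

    Candidate moves are evaluated in lexicographic (source, target, move-type)
    order and the first strictly score-improving move is accepted, which makes
    the search fully deterministic.  Additions are only allowed along skeleton
    edges; every accepted move keeps the graph acyclic.
    """
    if callable(score):
        user_score = score
        local = lambda node, parents: user_score(data, node, list(parents))  # noqa: E731
    elif score == "bic":
        if tester is None:
            tester = _FastTester(data)
        local = tester.local_bic
    else:
        raise ValueError(f"unknown score {score!r}")

    nodes = sorted(restrict.nodes)
    unknown = [v for v in nodes if v not in data]
    if unknown:
        raise KeyError(f"skeleton nodes not in data: {unknown}")
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    allowed = {frozenset(e) for e in restrict.edges}

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def node_score(node: str, parents: tuple[str, ...]) -> float:
        key = (node, parents)
        val = cache.get(key)
        if val is None:
            val = local(node, parents)
            cache[key] = val
        return val

    def parents_of(node: str) -> tuple[str, ...]:
        return tuple(sorted(graph.predecessors(node)))

    eps = 1e-9
    accepted = 0
    improved = True
    while improved:
        if accepted >= max_iter:
            logger.warning("hill climb stopped: max_iter=%d exhausted", max_iter)
            break
        improved = False
        for u in nodes:
            for v in nodes:
                if u == v or frozenset((u, v)) not in allowed:
                    continue
                if not graph.has_edge(u, v) and not graph.has_edge(v, u):
                    # addition u -> v
                    if _would_cycle(graph, u, v):
                        continue
                    old = node_score(v, parents_of(v))
                    new = node_score(v, tuple(sorted((*parents_of(v), u))))
                    if new - old > eps:
                        graph.add_edge(u, v)
                        improved = True
                elif graph.has_edge(u, v):
                    # deletion of u -> v
                    pv = parents_of(v)
                    pv_without = tuple(p for p in pv if p != u)
                    delta_del = node_score(v, pv_without) - node_score(v, pv)
                    if delta_del > eps:
                        graph.remove_edge(u, v)
                        improved = True
                    else:
                        # reversal u -> v  becomes  v -> u
                        graph.remove_edge(u, v)
                        if _would_cycle(graph, v, u):
                            graph.add_edge(u, v)
                            continue
                        pu = parents_of(u)
                        delta = (
                            node_score(v, pv_without)
                            - node_score(v, pv)
                            + node_score(u, tuple(sorted((*pu, v))))
                            - node_score(u, pu)
                        )
                        if delta > eps:
                            graph.add_edge(v, u)
                            improved = True
                        else:
                            graph.add_edge(u, v)
                if improved:
                    break
            if improved:
                break
        if improved:
            accepted += 1
            if trace is not None:
                trace.append(
                    sum(node_score(v, parents_of(v)) for v in nodes)
                )
    return graph


def learn_structure(
    data: CategoricalDataset,
    config: StructureConfig | None = None,
    tester: _FastTester | None = None,
) -> nx.DiGraph:
    """Hybrid learner: constraint-based skeleton, then restricted hill climb."""
    config = config or StructureConfig()
    if len(data.columns) < 2:
        g = nx.DiGraph()
        g.add_nodes_from(data.columns)
        return g
    if tester is None and config.score == "bic":
        tester = _FastTester(data)
    skeleton = learn_skeleton(
        data, alpha=config.alpha, max_sepset=config.max_sepset, tester=tester
    )
    return hill_climb(
        data, skeleton, score=config.score, max_iter=config.max_iter, tester=tester
    )
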