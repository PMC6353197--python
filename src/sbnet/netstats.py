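"""Importance measures on an averaged network.

Denseness, unweighted hop distance to the sedentary-behaviour node, per-cluster
mean distance, and stability-weighted betweenness centrality computed on the
subgraph of nodes connected to SB.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .bootstrap_averaging import AveragedNetwork
from .schema import SB_VARIABLE, VariableSchema

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkStatsReport",
    "denseness",
    "distance_to_target",
    "cluster_mean_distance",
    "weighted_betweenness_sb",
    "rank_top_nodes",
    "compute_stats",
]

#: marker used in CSV output for clusters with no connection to the target
NOT_APPLICABLE = "N.A."


@dataclasses.dataclass
class NetworkStatsReport:
    """Summary statistics of one averaged network."""

    denseness: float
    distances: dict[str, int | None]  # hops to target; None = not connected
    cluster_distances: dict[str, float | None]  # mean per cluster; None = N.A.
    betweenness: dict[str, float]
    top_nodes: list[tuple[str, float]]

    def to_dict(self) -> dict:
        return {
            "denseness": self.denseness,
            "distances": self.distances,
            "cluster_distances": self.cluster_distances,
            "betweenness": self.betweenness,
            "top_nodes": [[n, v] for n, v in self.top_nodes],
        }


def denseness(network: AveragedNetwork | nx.Graph) -> float:
    """Realised edges as a percentage of all possible undirected pairs."""
    g = network.graph if isinstance(network, AveragedNetwork) else network
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("denseness requires at least 2 nodes")
    return 100.0 * g.number_of_edges() / (n * (n - 1) / 2)


def distance_to_target(
    network: AveragedNetwork | nx.Graph, target: str = SB_VARIABLE
) -> dict[str, int | None]:
    """Unweighted shortest-path hop count from every node to the target.

    Nodes with no path to the target map to ``None``.
    """
    g = network.graph if isinstance(network, AveragedNetwork) else network
    if target not in g:
        raise ValueError(f"target node {target!r} not present in network")
    lengths = nx.single_source_shortest_path_length(g, target)
    return {node: lengths.get(node) for node in sorted(g.nodes)}


def cluster_mean_distance(
    distances: Mapping[str, int | None],
    schema: Iterable[VariableSchema],
    target: str = SB_VARIABLE,
) -> dict[str, float | None]:
    """Mean hop distance per SOS cluster over its connected nodes.

    The target itself is excluded.  A cluster maps to ``None`` exactly when
    none of its nodes is connected to the target; disconnected nodes are
    excluded from an otherwise finite mean.
    """
    cluster_of = {v.name: v.cluster for v in schema}
    unknown = sorted(set(distances) - set(cluster_of))
    if unknown:
        raise KeyError(f"nodes without a cluster assignment: {unknown}")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    members: dict[str, int] = {}
    for node, dist in distances.items():
        if node == target:
            continue
        cluster = cluster_of[node]
        members[cluster] = members.get(cluster, 0) + 1
        if dist is not None:
            sums[cluster] = sums.get(cluster, 0.0) + dist
            counts[cluster] = counts.get(cluster, 0) + 1
    return {
        cluster: (sums[cluster] / counts[cluster] if counts.get(cluster) else None)
        for cluster in sorted(members)
    }


def weighted_betweenness_sb(
    network: AveragedNetwork | nx.Graph,
    target: str = SB_VARIABLE,
    weight_mode: str = "inverse",
    normalized: bool = True,
) -> dict[str, float]:
    """Stability-weighted betweenness on the subgraph connected to the target.

    Edge traversal cost is ``1/strength`` (``weight_mode='inverse'``, default:
    stable edges shorten paths) or ``1 - strength`` (``weight_mode='one_minus'``).
    Values are normalised by the number of node pairs of the subgraph so they
    are comparable across strata of different connectivity.
    """
    g = network.graph if isinstance(network, AveragedNetwork) else network
    if target not in g:
        raise ValueError(f"target node {target!r} not present in network")
    if weight_mode not in ("inverse", "one_minus"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    component = nx.node_connected_component(g, target)
    sub = g.subgraph(component).copy()
    if sub.number_of_nodes() < 3:
        logger.warning(
            "target subgraph has %d node(s); betweenness is all zero",
            sub.number_of_nodes(),
        )
        return {node: 0.0 for node in sorted(sub.nodes)}
    for u, v, d in sub.edges(data=True):
        s = d.get("strength", 1.0)
        d["cost"] = 1.0 / s if weight_mode == "inverse" else 1.0 - s
    bc = nx.betweenness_centrality(sub, weight="cost", normalized=normalized)
    return {node: bc[node] for node in sorted(sub.nodes)}


def rank_top_nodes(
    betweenness: Mapping[str, float],
    k: int = 2,
    exclude: Sequence[str] = (SB_VARIABLE,),
) -> list[tuple[str, float]]:
    """Top-k nodes by centrality; ties at the k-th rank are all reported.

    Nodes listed in ``exclude`` (the target by default) never appear.  An
    all-zero centrality map yields an empty ranking.
    """
    items = [
        (name, value)
        for name, value in betweenness.items()
        if name not in exclude and value > 0.0
    ]
    if not items:
        logger.warning("all centralities are zero; returning empty ranking")
        return []
    items.sort(key=lambda nv: (-nv[1], nv[0]))
    if len(items) <= k:
        return items
    cutoff = items[k - 1][1]
    return [nv for nv in items if nv[1] >= cutoff - 1e-15]


def compute_stats(
    network: AveragedNetwork,
    schema: Iterable[VariableSchema],
    target: str = SB_VARIABLE,
    k: int = 2,
    weight_mode: str = "inverse",
) -> NetworkStatsReport:
    """All statistics of one averaged network in a single report."""
    schema = list(schema)
    dists = distance_to_target(network, target)
    bc = weighted_betweenness_sb(network, target, weight_mode=weight_mode)
    return NetworkStatsReport(
        denseness=denseness(network),
        distances=dists,
        cluster_distances=cluster_mean_distance(dists, schema, target),
        betweenness=bc,
        top_nodes=rank_top_nodes(bc, k=k, exclude=(target,)),
    )


def format_distance(value: float | None, digits: int = 2) -> str:
    if value is None:
        return NOT_APPLICABLE
    if isinstance(value, float) and math.isnan(value):
        return NOT_APPLICABLE
    return f"{value:.{digits}f}"
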