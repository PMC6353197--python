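"""Bootstrap resampling, edge-stability estimation and averaged networks.

Each replicate is a with-replacement resample of size ``n``; a network is
learned per replicate and an edge's stability is the fraction of replicates
containing it in either orientation.  Edges at or above the inclusion
threshold (default 40%) form the averaged network, classed *strong* at >= 70%
stability and *weak* below.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .bnlearn_core import StructureConfig, _FastTester, learn_structure
from .dataset import CategoricalDataset

__all__ = [
    "EdgeStrengthTable",
    "AveragedNetwork",
    "to_undirected",
    "bootstrap_networks",
    "average_network",
]

STRONG_THRESHOLD = 0.70


def to_undirected(graph: nx.DiGraph) -> set[frozenset]:
    """Drop arc directions and collapse duplicate pairs."""
    return {frozenset((u, v)) for u, v in graph.edges}


@dataclasses.dataclass
class EdgeStrengthTable:
    """Per-pair bootstrap stability of edges.

    ``counts`` maps unordered node pairs to the number of replicates whose
    learned network contained the pair (in either orientation);
    ``directed_counts`` keeps per-orientation frequencies for diagnostics.
    """

    nodes: list[str]
    n_replicates: int
    counts: dict[frozenset, int]
    directed_counts: dict[tuple[str, str], int] = dataclasses.field(default_factory=dict)

    def strength(self, u: str, v: str) -> float:
        return self.counts.get(frozenset((u, v)), 0) / self.n_replicates

    def strengths(self) -> dict[frozenset, float]:
        return {pair: c / self.n_replicates for pair, c in self.counts.items() if c > 0}

    def to_frame(self, threshold: float = 0.0) -> pd.DataFrame:
        rows = []
        for pair, c in sorted(self.counts.items(), key=lambda kv: tuple(sorted(kv[0]))):
            s = c / self.n_replicates
            if s <= 0 or s < threshold:
                continue
            u, v = sorted(pair)
            cls = "strong" if s >= STRONG_THRESHOLD else "weak"
            rows.append({"node1": u, "node2": v, "strength": s, "class": cls})
        return pd.DataFrame(rows, columns=["node1", "node2", "strength", "class"])

    def to_csv(self, path, threshold: float = 0.0) -> None:
        self.to_frame(threshold).to_csv(path, index=False)


@dataclasses.dataclass
class AveragedNetwork:
    """Undirected graph of edges whose stability met the inclusion threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, str]]:
        return sorted(
            (*sorted((u, v)), d["strength"], d["stability"])
            for u, v, d in self.graph.edges(data=True)
        )

    def strength(self, u: str, v: str) -> float:
        return self.graph[u][v]["strength"]


def bootstrap_networks(
    data: CategoricalDataset,
    replicates: int,
    config: StructureConfig | None = None,
    seed: int = 0,
) -> EdgeStrengthTable:
    """Learn one network per bootstrap resample and tally edge occurrence.

    Each replicate draws its resample from an independent substream of the
    master seed (indexed by replicate number), so results are reproducible and
    independent of any execution order.  Resamples are applied as row
    multiplicity weights, which lets all replicates share the cached code
    columns of the original data.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if data.n_rows == 0:
        raise ValueError("cannot bootstrap an empty dataset")
    config = config or StructureConfig()
    n = data.n_rows
    tester = _FastTester(data)
    counts: dict[frozenset, int] = {}
    directed: dict[tuple[str, str], int] = {}
    for rep in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence([713311, int(seed), rep]))
        multiplicity = np.bincount(rng.integers(0, n, size=n), minlength=n)
        tester.set_weights(multiplicity.astype(np.float64))
        graph = learn_structure(data, config, tester=tester)
        for u, v in graph.edges:
            directed[(u, v)] = directed.get((u, v), 0) + 1
        for pair in to_undirected(graph):
            counts[pair] = counts.get(pair, 0) + 1
    tester.set_weights(None)
    return EdgeStrengthTable(sorted(data.columns), replicates, counts, directed)


def average_network(
    strengths: EdgeStrengthTable, threshold: float = 0.40
) -> AveragedNetwork:
    """Keep pairs with stability >= threshold; label strong/weak at 70%."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(strengths.nodes)
    for pair, count in sorted(strengths.counts.items(), key=lambda kv: tuple(sorted(kv[0]))):
        s = count / strengths.n_replicates
        if s >= threshold:
            u, v = sorted(pair)
            cls = "strong" if s >= STRONG_THRESHOLD else "weak"
            g.add_edge(u, v, strength=s, stability=cls)
    return AveragedNetwork(g, threshold)


def annotate_clusters(network: AveragedNetwork, schema: Iterable) -> None:
    """Attach the SOS cluster of each variable as a node attribute."""
    clusters = {v.name: v.cluster for v in schema}
    for node in network.graph.nodes:
        if node in clusters:
            network.graph.nodes[node]["cluster"] = clusters[node]
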