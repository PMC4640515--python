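"""Network topology metrics: clustering coefficient, betweenness, components.

These are the NetworkAnalyzer-style per-node statistics used to read the
gene-sharing network: a dense, taxonomically coherent group shows clustering
coefficients near 1, while bridge (mosaic) genomes stand out by high
betweenness centrality.  Metrics are computed on the unweighted skeleton by
default; the weighted betweenness variant uses distance = 1/Sig.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Hashable, List, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "clustering_coefficient",
    "betweenness",
    "components",
    "TopologyReport",
    "topology_report",
]


def clustering_coefficient(graph: nx.Graph) -> Tuple[Dict[Hashable, float], float]:
    """Per-node unweighted clustering coefficient and its mean.

    CC(v) = 2 e(N(v)) / (deg(v) (deg(v)-1)); nodes of degree < 2 score 0.
    """
    cc = nx.clustering(graph)
    mean = sum(cc.values()) / len(cc) if cc else 0.0
    return dict(cc), mean


def betweenness(
    graph: nx.Graph, weighted: bool = False
) -> Tuple[Dict[Hashable, float], Dict[Hashable, float]]:
    """Exact shortest-path betweenness centrality (raw, normalized).

    Raw values count each unordered pair once; normalization divides by
    (n-1)(n-2)/2 with the whole-graph n (NetworkAnalyzer's convention), so
    graphs with fewer than 3 nodes normalize to all zeros.  In weighted mode
    edge distance is 1/Sig, so heavier (more similar) edges are shorter.
    """
    if weighted:
        dist_graph = graph.copy()
        for u, v, data in dist_graph.edges(data=True):
            data["distance"] = 1.0 / float(data.get("weight", 1.0))
        raw = nx.betweenness_centrality(dist_graph, normalized=False, weight="distance")
    else:
        raw = nx.betweenness_centrality(graph, normalized=False)
    n = graph.number_of_nodes()
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    norm = {v: raw[v] * scale for v in raw}
    return dict(raw), norm


def components(graph: nx.Graph) -> Tuple[int, List[int]]:
    """Connected-component count and sizes, sorted descending."""
    sizes = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    return len(sizes), sizes


@dataclass
class TopologyReport:
    """Per-node degree/CC/BC table plus graph-level summaries."""

    table: pd.DataFrame  # node, degree, cc, bc_raw, bc_norm
    mean_cc: float
    n_components: int
    component_sizes: List[int]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_summary_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean_cc": self.mean_cc,
                    "n_components": self.n_components,
                    "component_sizes": self.component_sizes,
                },
                fh,
                indent=2,
            )


def topology_report(graph: nx.Graph, weighted_bc: bool = False) -> TopologyReport:
    """Full topology report for a network."""
    cc, mean_cc = clustering_coefficient(graph)
    bc_raw, bc_norm = betweenness(graph, weighted=weighted_bc)
    n_comp, sizes = components(graph)
    nodes = sorted(graph.nodes, key=str)
    table = pd.DataFrame(
        {
            "node": nodes,
            "degree": [graph.degree(v) for v in nodes],
            "cc": [cc[v] for v in nodes],
            "bc_raw": [bc_raw[v] for v in nodes],
            "bc_norm": [bc_norm[v] for v in nodes],
        }
    )
    return TopologyReport(table, mean_cc, n_comp, sizes)
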