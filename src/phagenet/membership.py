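"""Node-to-cluster membership: quantifying mosaicism in the network.

After MCL partitions the network, each node's affiliation need not be
all-or-nothing: a mosaic phage keeps edges into several clusters.  The
membership of node n in cluster k is the proportion of n's total incident
edge weight (Sig, or plain edge count in unweighted mode) carried by edges
to members of cluster k.  Rows of the resulting matrix are the pie wedges of
the classic gene-sharing-network figures; a row spread over several clusters
is the signature of a mosaic or bridge genome.
"""

from __future__ import annotations

import warnings
from typing import Dict, Hashable

import networkx as nx
import pandas as pd

from .mcl import Clustering

__all__ = ["membership_matrix", "wedge_table", "multi_cluster_report"]


def membership_matrix(
    graph: nx.Graph, clustering: Clustering, weighted: bool = True
) -> pd.DataFrame:
    """Row-stochastic node x cluster matrix of edge-weight proportions.

    m(n, k) = sum of w(n, u) over u in cluster k, divided by node n's total
    incident weight.  Self-loops are excluded: self-similarity is not
    evidence of affiliation.  A node with no incident edges gets membership
    1 in its own cluster (with a warning).
    """
    missing = set(graph.nodes) - set(clustering.cluster_of)
    if missing:
        raise ValueError(
            f"clustering does not cover nodes: {sorted(missing, key=str)[:5]}"
        )
    cluster_ids = sorted(set(clustering.cluster_of.values()))
    nodes = sorted(graph.nodes, key=str)
    mat = pd.DataFrame(0.0, index=nodes, columns=cluster_ids)
    isolated = []
    for node in nodes:
        total = 0.0
        sums: Dict[int, float] = {}
        for _, nbr, data in graph.edges(node, data=True):
            if nbr == node:
                continue
            w = float(data.get("weight", 1.0)) if weighted else 1.0
            k = clustering.cluster_of[nbr]
            sums[k] = sums.get(k, 0.0) + w
            total += w
        if total == 0.0:
            isolated.append(node)
            mat.loc[node, clustering.cluster_of[node]] = 1.0
        else:
            for k, s in sums.items():
                mat.loc[node, k] = s / total
    if isolated:
        warnings.warn(
            f"{len(isolated)} node(s) without incident edges assigned full "
            "membership to their own cluster",
            stacklevel=2,
        )
    return mat


def wedge_table(matrix: pd.DataFrame, display_threshold: float = 0.01) -> pd.DataFrame:
    """Long-form (node, cluster, proportion) rows above the display threshold.

    Entries <= ``display_threshold`` are pooled into one ``other`` wedge per
    node (omitted when zero), so each node's retained wedges sum to 1.
    """
    rows = []
    for node, row in matrix.iterrows():
        other = 0.0
        for cluster, prop in row.items():
            if prop > display_threshold:
                rows.append({"node": node, "cluster": cluster, "proportion": prop})
            else:
                other += prop
        if other > 0:
            rows.append({"node": node, "cluster": "other", "proportion": other})
    return pd.DataFrame(rows, columns=["node", "cluster", "proportion"])


def multi_cluster_report(
    matrix: pd.DataFrame, assign_threshold: float = 0.01
) -> Dict[Hashable, int]:
    """Per node, how many clusters hold membership above the threshold.

    Pure members score 1; bridge/mosaic genomes score higher (the criterion
    under which KP34-like phages span five or six clusters).
    """
    return {
        node: int((row > assign_threshold).sum()) for node, row in matrix.iterrows()
    }
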