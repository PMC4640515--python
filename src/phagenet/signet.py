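"""Hypergeometric Sig-score gene-sharing network.

Two genomes that share many protein families out of a universe of N are
unlikely to do so by chance.  The tail probability of the shared count under
the hypergeometric null — drawing genome B's repertoire at random from the N
families and counting the overlap with genome A's — is corrected for the
number of pairwise comparisons T and turned into the edge weight

    Sig = max(0, -log10(p * T)),

so Sig = 3 means the shared repertoire is ~1000x beyond chance after
correction.  Genome pairs with Sig above a threshold (default 1) form the
weighted, undirected gene-sharing network.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .families import ProfileMatrix

__all__ = [
    "hypergeom_pvalue",
    "sig_score",
    "build_network",
    "export_graph",
    "read_graph",
]

SIG_MAX_DEFAULT = 300.0


def hypergeom_pvalue(a: int, b: int, c: int, n_total: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= c families.

    Genome A carries ``a`` of the ``n_total`` families, genome B carries
    ``b``; returns P(X >= c) for X ~ Hypergeometric(n_total, a, b), i.e.
    sum_{i=c}^{min(a,b)} C(a,i) C(n_total-a, b-i) / C(n_total, b).  Summation
    is done in log space (log-gamma binomials + logsumexp), so the value is
    stable for family universes in the thousands.  Symmetric in (a, b).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= a <= n_total and 0 <= b <= n_total):
        raise ValueError(f"repertoire sizes must lie in [0, {n_total}]")
    if not 0 <= c <= min(a, b):
        raise ValueError(f"shared count {c} outside [0, min({a}, {b})]")
    if c == 0:
        return 1.0
    return float(min(1.0, math.exp(_log_tail(a, b, c, n_total))))


def _log_tail(a: int, b: int, c: int, n_total: int) -> float:
    """Natural log of the hypergeometric upper tail (c >= 1, bounds checked)."""
    if a > b:
        a, b = b, a  # canonical order makes symmetry exact, not just analytic
    i = np.arange(c, min(a, b) + 1)

    def log_binom(n: float, k: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_terms = (
        log_binom(a, i) + log_binom(n_total - a, b - i) - log_binom(n_total, b)
    )
    return min(0.0, float(logsumexp(log_terms)))


def sig_score(p: float, n_comparisons: int, sig_max: float = SIG_MAX_DEFAULT) -> float:
    """Sig = max(0, -log10(p * T)), the comparison-corrected edge weight."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if p < 0 or p > 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p == 0:
        warnings.warn(
            f"p-value underflowed to 0; Sig capped at {sig_max}", stacklevel=2
        )
        return sig_max
    return max(0.0, -(math.log10(p) + math.log10(n_comparisons)))


def build_network(
    profile: ProfileMatrix,
    sig_threshold: float = 1.0,
    n_comparisons: Optional[int] = None,
    sig_max: float = SIG_MAX_DEFAULT,
) -> nx.Graph:
    """Weighted gene-sharing network from a presence/absence profile.

    Every unordered genome pair is scored: c = shared families, a and b the
    repertoire sizes, N the profile's family count, T = n(n-1)/2 unless
    ``n_comparisons`` overrides it.  Pairs with Sig strictly above
    ``sig_threshold`` become edges weighted by Sig.  The graph carries the
    threshold, N and T used as graph attributes; all genomes appear as nodes
    even if isolated.
    """
    genomes = profile.genomes
    if len(genomes) < 2:
        raise ValueError("profile must contain at least 2 genomes")
    n = len(genomes)
    t_comp = n_comparisons if n_comparisons is not None else n * (n - 1) // 2
    sizes = profile.repertoire_sizes()
    shared = profile.shared_counts()
    n_fam = profile.n_families

    graph = nx.Graph(sig_threshold=sig_threshold, n_families=n_fam, n_comparisons=t_comp)
    graph.add_nodes_from(genomes)
    for i in range(n):
        for j in range(i + 1, n):
            c = int(shared[i, j])
            if c == 0:
                continue
            # Sig straight from the log tail: immune to p underflowing to 0
            log10_p = _log_tail(int(sizes[i]), int(sizes[j]), c, n_fam) / math.log(10)
            sig = max(0.0, min(sig_max, -(log10_p + math.log10(t_comp))))
            if sig > sig_threshold:
                graph.add_edge(genomes[i], genomes[j], weight=sig)
    return graph


_FORMATS = ("edge-tsv", "sif", "graphml")


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Write the network as Cytoscape-readable edge-TSV, SIF or GraphML."""
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(_FORMATS)}")
    if fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsig\n")
            for u, v, w in sorted(graph.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{w:.6f}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            seen = set()
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\tsig\t{v}\n")
                seen.update((u, v))
            for node in sorted(set(graph.nodes) - seen):
                fh.write(f"{node}\n")
    else:
        nx.write_graphml(graph, path)


def read_graph(path: str | Path, fmt: Optional[str] = None) -> nx.Graph:
    """Read a network written by :func:`export_graph` (edge-TSV or GraphML)."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "edge-tsv"
    if fmt == "graphml":
        return nx.read_graphml(path)
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "source\ttarget\tsig":
            raise ValueError(f"{path}: not an edge-TSV file")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            graph.add_edge(u, v, weight=float(w))
    return graph
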