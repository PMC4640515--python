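"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration and plain
Python loops — and shares no code path with phagenet.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from typing import Dict, FrozenSet, Hashable, List, Mapping, Set, Tuple


def hypergeom_tail_by_enumeration(a: int, b: int, c: int, n_total: int) -> float:
    """P(overlap >= c) by enumerating every size-b subset of the universe."""
    universe = range(n_total)
    a_set = set(range(a))
    hits = total = 0
    for draw in combinations(universe, b):
        total += 1
        if len(a_set.intersection(draw)) >= c:
            hits += 1
    return hits / total


def naive_mcl_partition(
    nodes: List[Hashable],
    weights: Mapping[Tuple[Hashable, Hashable], float],
    inflation: float,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> Set[FrozenSet[Hashable]]:
    """Loop-based dense MCL returning the partition as a set of frozensets."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mat = [[0.0] * n for _ in range(n)]
    for (u, v), w in weights.items():
        mat[idx[u]][idx[v]] = w
        mat[idx[v]][idx[u]] = w
    for i in range(n):
        incident = max(mat[i]) if max(mat[i]) > 0 else 1.0
        mat[i][i] = incident
    def normalize(m):
        for j in range(n):
            s = sum(m[i][j] for i in range(n))
            for i in range(n):
                m[i][j] /= s
    normalize(mat)
    for _ in range(max_iter):
        sq = [[sum(mat[i][k] * mat[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        new = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        normalize(new)
        diff = max(abs(new[i][j] - mat[i][j]) for i in range(n) for j in range(n))
        mat = new
        if diff < tol:
            break
    attractors = [i for i in range(n) if mat[i][i] > 1e-6]
    clusters: List[Set[int]] = []
    for att in attractors:
        members = {j for j in range(n) if mat[att][j] > 1e-6} | {att}
        for cl in clusters:
            if cl & members:
                cl |= members
                break
        else:
            clusters.append(members)
    # merge transitively overlapping systems
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    assigned = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in assigned:
            clusters.append({j})
    return {frozenset(nodes[i] for i in cl) for cl in clusters}


def exhaustive_betweenness(adjacency: Mapping[Hashable, Set[Hashable]]) -> Dict[Hashable, float]:
    """Raw betweenness by enumerating every shortest path of every pair."""
    nodes = sorted(adjacency, key=str)
    bc = {v: 0.0 for v in nodes}

    def bfs_dist(src):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for w in adjacency[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        return dist

    def all_shortest_paths(s, t, dist_from_s):
        if t not in dist_from_s:
            return []
        target_len = dist_from_s[t]
        paths = []

        def dfs(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            if len(path) - 1 >= target_len:
                return
            for w in adjacency[u]:
                if w not in path and dist_from_s.get(w, 10 ** 9) == len(path):
                    path.append(w)
                    dfs(path)
                    path.pop()

        dfs([s])
        return paths

    for i, s in enumerate(nodes):
        dist = bfs_dist(s)
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t, dist)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc
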