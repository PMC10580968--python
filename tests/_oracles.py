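"""Independent brute-force oracles used by the tests.

All graph quantities are recomputed here from first principles (explicit
BFS shortest-path enumeration), deliberately avoiding the library code and
networkx so they can arbitrate both.
"""

from __future__ import annotations

import itertools
from collections import deque


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_shortest_paths(adj: dict, s, t, dist):
    """Enumerate every shortest s-t path explicitly."""
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v, -1) == dist[u] + 1 and dist[v] <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_force_metrics(edges, nodes):
    """degree, normalized betweenness, harmonic closeness, clustering,
    and largest-component diameter, all by explicit enumeration."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}

    betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for s in nodes:
        dist = bfs_distances(adj, s)
        closeness[s] = (sum(1.0 / d for v, d in dist.items() if d > 0)
                        / (n - 1) if n > 1 else 0.0)
        for t in nodes:
            if t <= s or t not in dist or t == s:
                continue
            paths = all_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                betweenness[v] += through / len(paths)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    betweenness = {v: b * norm for v, b in betweenness.items()}

    clustering = {}
    for v in nodes:
        nb = list(adj[v])
        k = len(nb)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2)
                    if b in adj[a])
        clustering[v] = 2.0 * links / (k * (k - 1))

    # largest component + diameter
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    giant = max(comps, key=len)
    diameter = 0
    for s in giant:
        dist = bfs_distances(adj, s)
        diameter = max(diameter, max(dist[v] for v in giant))

    return {"degree": degree, "betweenness": betweenness,
            "closeness": closeness, "clustering": clustering,
            "diameter": diameter}
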