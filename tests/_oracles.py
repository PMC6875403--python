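"""Independent brute-force oracles used across the test suite.

Everything here is written from first principles (hand-rolled BFS, explicit
path enumeration, exact rational combinatorics, dense eigensolvers) so the
oracles share no code path with the implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    """Hand-rolled BFS distance map from ``source`` (reachable nodes only)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def _all_simple_paths(adj, s, t, max_len):
    """All simple paths s->t up to max_len edges, by explicit DFS."""
    out = []
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            out.append(path)
            continue
        if len(path) - 1 >= max_len:
            continue
        for w in adj[u]:
            if w not in path:
                stack.append((w, path + [w]))
    return out


def bf_betweenness(nodes, edges):
    """Unnormalized betweenness by exhaustive shortest-path enumeration.

    Each unordered pair {s, t} contributes sigma_st(v)/sigma_st once;
    disconnected pairs contribute nothing.  Only viable for tiny graphs.
    """
    adj = adjacency(nodes, edges)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(sorted(nodes), 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        paths = _all_simple_paths(adj, s, t, dist[t])
        shortest = [p for p in paths if len(p) - 1 == dist[t]]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    return bc


def bf_closeness(nodes, edges):
    """Component-relative closeness from hand-rolled BFS distances."""
    adj = adjacency(nodes, edges)
    cc = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        m = len(dist)  # component size
        total = sum(d for u, d in dist.items() if u != v)
        cc[v] = (m - 1) / total if total > 0 else 0.0
    return cc


def bf_eigenvector(nodes, edges):
    """Principal adjacency eigenvector from a dense symmetric eigensolver."""
    order = sorted(nodes)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    if not edges:
        return {v: 0.0 for v in order}, 0.0
    w, vecs = np.linalg.eigh(a)
    lead = vecs[:, np.argmax(w)]
    lead = np.abs(lead)
    lead = lead / np.linalg.norm(lead)
    return {v: float(lead[idx[v]]) for v in order}, float(np.max(w))


def bf_network_centrality(nodes, edges):
    """NC via direct common-neighbor enumeration per incident edge."""
    adj = adjacency(nodes, edges)
    nc = {v: 0.0 for v in nodes}
    for v in nodes:
        for u in adj[v]:
            den = min(len(adj[v]) - 1, len(adj[u]) - 1)
            if den > 0:
                nc[v] += len(adj[v] & adj[u]) / den
    return nc


def bf_lac(nodes, edges):
    """LAC via explicit induced-subgraph degree computation."""
    adj = adjacency(nodes, edges)
    lac = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        if not nbrs:
            lac[v] = 0.0
            continue
        induced_deg = 0
        for a, b in combinations(nbrs, 2):
            if b in adj[a]:
                induced_deg += 2
        lac[v] = induced_deg / len(nbrs)
    return lac


def bf_hypergeom_upper(k, K, n, N):
    """Exact rational upper-tail hypergeometric probability."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def bf_kappa(a, b, universe):
    """Cohen's kappa of membership indicators, via sklearn's 2x2 oracle."""
    from sklearn.metrics import cohen_kappa_score

    order = sorted(universe)
    ya = [1 if g in a else 0 for g in order]
    yb = [1 if g in b else 0 for g in order]
    return float(cohen_kappa_score(ya, yb))
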