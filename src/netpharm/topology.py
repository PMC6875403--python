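"""Six node centralities and strict-median hub selection.

Hub targets are defined as nodes whose degree (DC), betweenness (BC),
closeness (CC), eigenvector (EC), network (NC) and local-average-
connectivity (LAC) centralities all strictly exceed the network-wide
medians.  The definitions follow the CytoNCA conventions used in topological
screening of PPI networks:

DC(v)
    Number of neighbors.
BC(v)
    Unnormalized shortest-path betweenness, each unordered pair {s, t}
    counted once; disconnected pairs contribute 0.
CC(v)
    Component-relative closeness: (m - 1) / sum of distances to the other
    m - 1 nodes of v's component; an isolated node scores 0.
EC(v)
    Entry of the nonnegative principal eigenvector of the adjacency matrix,
    Euclidean-norm 1, computed on the full (possibly disconnected) matrix.
NC(v)
    Sum over neighbors u of the edge clustering coefficient
    ECC(v, u) = z(v, u) / min(DC(v) - 1, DC(u) - 1), with z the number of
    common neighbors; a zero denominator contributes 0.
LAC(v)
    Mean degree of v's neighbors within the subgraph they induce, i.e.
    2 * (triangles through v) / DC(v); a degree-0 node scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from netpharm.ppi import PPIGraph

#: Power-iteration convergence tolerance on the max successive-iterate change.
EC_TOL = 1e-10
#: Power-iteration cap.
EC_MAX_ITER = 1000


@dataclass(frozen=True)
class CentralityRecord:
    """The six topological scores of one node."""

    node: str
    dc: int
    bc: float
    cc: float
    ec: float
    nc: float
    lac: float

    def __post_init__(self) -> None:
        for name in ("bc", "cc", "ec", "nc", "lac"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{self.node}: non-finite {name}")
        if self.cc > 1.0 + 1e-12:
            raise ValueError(f"{self.node}: cc must be <= 1, got {self.cc}")

    def values(self) -> tuple[float, float, float, float, float, float]:
        return (float(self.dc), self.bc, self.cc, self.ec, self.nc, self.lac)


@dataclass(frozen=True)
class HubThresholds:
    """Per-metric medians and the selection comparison rule."""

    dc_med: float
    bc_med: float
    cc_med: float
    ec_med: float
    nc_med: float
    lac_med: float
    strict: bool = True

    def values(self) -> tuple[float, float, float, float, float, float]:
        return (self.dc_med, self.bc_med, self.cc_med, self.ec_med, self.nc_med, self.lac_med)


def degree_centrality(g: PPIGraph) -> dict[str, int]:
    """DC(v) = |N(v)|."""
    adj = g.adjacency()
    return {v: len(adj[v]) for v in g.nodes}


def betweenness_centrality(g: PPIGraph) -> dict[str, float]:
    """Unnormalized betweenness, each unordered pair counted once."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return {str(v): float(x) for v, x in bc.items()}


def closeness_centrality(g: PPIGraph) -> dict[str, float]:
    """Component-relative closeness; isolated nodes score 0."""
    cc = nx.closeness_centrality(g.to_networkx(), wf_improved=False)
    return {str(v): float(x) for v, x in cc.items()}


def eigenvector_centrality(g: PPIGraph) -> dict[str, float]:
    """Principal eigenvector of the adjacency matrix, Euclidean-norm 1.

    Computed by power iteration on the full adjacency matrix; in a
    disconnected graph the mass concentrates on the component(s) with the
    largest spectral radius.  A graph without edges yields all zeros with a
    warning.
    """
    order = sorted(g.nodes)
    n = len(order)
    if g.n_edges == 0:
        if n:
            warnings.warn("eigenvector centrality of an edgeless graph is zero", stacklevel=2)
        return {v: 0.0 for v in order}
    idx = {v: i for i, v in enumerate(order)}
    a = np.zeros((n, n))
    for u, v in g.edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(EC_MAX_ITER):
        # +I shift keeps the eigenvectors but makes the principal eigenvalue
        # strictly dominant, so the iteration converges on bipartite graphs too
        y = a @ x + x
        norm = np.linalg.norm(y)
        y /= norm
        if np.max(np.abs(y - x)) < EC_TOL:
            x = y
            break
        x = y
    return {v: float(x[idx[v]]) for v in order}


def network_centrality(g: PPIGraph) -> dict[str, float]:
    """NC(v): sum of edge clustering coefficients over incident edges."""
    adj = g.adjacency()
    nc = {v: 0.0 for v in g.nodes}
    for u, v in g.edges:
        du, dv = len(adj[u]), len(adj[v])
        den = min(du - 1, dv - 1)
        if den <= 0:
            continue
        z = len(adj[u] & adj[v])
        ecc = z / den
        nc[u] += ecc
        nc[v] += ecc
    return nc


def local_average_connectivity(g: PPIGraph) -> dict[str, float]:
    """LAC(v) = 2 * triangles(v) / DC(v); 0 for isolated nodes."""
    adj = g.adjacency()
    lac: dict[str, float] = {}
    for v in g.nodes:
        nbrs = adj[v]
        d = len(nbrs)
        if d == 0:
            lac[v] = 0.0
            continue
        # induced-neighborhood degree sum = 2 * triangles through v
        deg_sum = sum(len(adj[u] & nbrs) for u in nbrs)
        lac[v] = deg_sum / d
    return lac


def centrality_table(g: PPIGraph) -> list[CentralityRecord]:
    """One record per node with all six metrics, sorted by node id."""
    if g.n_nodes == 0:
        return []
    dc = degree_centrality(g)
    bc = betweenness_centrality(g)
    cc = closeness_centrality(g)
    ec = eigenvector_centrality(g)
    nc = network_centrality(g)
    lac = local_average_connectivity(g)
    return [
        CentralityRecord(
            node=v, dc=dc[v], bc=bc[v], cc=cc[v], ec=ec[v], nc=nc[v], lac=lac[v]
        )
        for v in sorted(g.nodes)
    ]


def median_thresholds(table: list[CentralityRecord], strict: bool = True) -> HubThresholds:
    """Per-metric sample medians of a centrality table.

    The median of an even-length sample is the arithmetic mean of the two
    middle order statistics.
    """
    if not table:
        raise ValueError("cannot take medians of an empty centrality table")
    cols = np.array([r.values() for r in table], dtype=float)
    meds = np.median(cols, axis=0)
    return HubThresholds(
        dc_med=float(meds[0]),
        bc_med=float(meds[1]),
        cc_med=float(meds[2]),
        ec_med=float(meds[3]),
        nc_med=float(meds[4]),
        lac_med=float(meds[5]),
        strict=strict,
    )


def select_hubs(table: list[CentralityRecord], thr: HubThresholds) -> list[str]:
    """Nodes exceeding every one of the six thresholds.

    With ``thr.strict`` (the default) the comparison is strict (>) on all
    six metrics, so no more than floor(n/2) nodes can ever be selected.
    Output is deterministically sorted.
    """
    t = thr.values()
    hubs = []
    for r in table:
        v = r.values()
        if thr.strict:
            ok = all(x > m for x, m in zip(v, t))
        else:
            ok = all(x >= m for x, m in zip(v, t))
        if ok:
            hubs.append(r.node)
    return sorted(hubs)
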