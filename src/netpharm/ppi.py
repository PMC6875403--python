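"""Protein-protein interaction (PPI) graphs, seed networks and the CPPI merge.

The pipeline treats PPI data as an undirected, unweighted simple graph:
self-interactions are dropped and duplicate assertions (in either
orientation) collapse to one edge.  From a background PPI snapshot two seed
networks are extracted — one around the predicted drug targets, one around
the known disease targets — and merged into the core PPI (CPPI) network on
which hub selection runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import networkx as nx

SeedMode = Literal["induced", "induced_plus_bridges", "first_neighbors"]
MergeMode = Literal["node_intersection", "union"]

_SEED_MODES = ("induced", "induced_plus_bridges", "first_neighbors")
_MERGE_MODES = ("node_intersection", "union")


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PPIGraph:
    """Undirected simple graph over protein identifiers.

    Invariants: no self-loops, no duplicate edges (edges are stored as
    lexicographically sorted pairs), every edge endpoint is in ``nodes``.
    Isolated nodes are permitted (an induced seed network can produce them).
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != _canon(u, v):
                raise ValueError(f"edge {(u, v)!r} not in canonical order")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {(u, v)!r} has endpoint outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "PPIGraph":
        edges = frozenset(_canon(str(u), str(v)) for u, v in g.edges() if u != v)
        return cls(nodes=frozenset(str(n) for n in g.nodes()), edges=edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj


@dataclass(frozen=True)
class SeedNetworkConfig:
    """How to expand a seed set into a subnetwork of the background PPI.

    ``induced``
        Subgraph induced on the seeds alone.
    ``induced_plus_bridges`` (default)
        Seeds plus every non-seed adjacent to at least two distinct seeds,
        with all edges among the admitted nodes.  This is the smallest
        expansion consistent with the node growth seed-network builders such
        as BisoGenet exhibit.
    ``first_neighbors``
        Seeds plus all their neighbors, induced.
    """

    mode: SeedMode = "induced_plus_bridges"

    def __post_init__(self) -> None:
        if self.mode not in _SEED_MODES:
            raise ValueError(f"unknown seed mode {self.mode!r}; choose from {_SEED_MODES}")


@dataclass(frozen=True)
class MergeConfig:
    """How two seed networks merge into the CPPI.

    ``node_intersection`` (default) keeps the nodes present in both networks
    and every edge of either network among them; ``union`` is the
    componentwise union.
    """

    mode: MergeMode = "node_intersection"

    def __post_init__(self) -> None:
        if self.mode not in _MERGE_MODES:
            raise ValueError(f"unknown merge mode {self.mode!r}; choose from {_MERGE_MODES}")


def build_graph(pairs: Iterable[tuple[str, str]]) -> PPIGraph:
    """Canonicalize raw interaction pairs into a simple undirected graph.

    Self-pairs are dropped; duplicates in either orientation collapse; the
    node set is exactly the endpoints of the surviving edges.
    """
    edges = {_canon(u, v) for u, v in pairs if u != v}
    nodes = frozenset(n for e in edges for n in e)
    return PPIGraph(nodes=nodes, edges=frozenset(edges))


def seed_network(
    ppi: PPIGraph, seeds: set[str], config: SeedNetworkConfig | None = None
) -> PPIGraph:
    """Extract the subnetwork around ``seeds`` from a background PPI.

    Raises
    ------
    ValueError
        If ``seeds`` is empty, or none of the seeds occur in the graph
        (the error reports how many seeds were missing).
    """
    config = config or SeedNetworkConfig()
    if not seeds:
        raise ValueError("seed set is empty")
    found = seeds & ppi.nodes
    if not found:
        raise ValueError(f"no seed found in PPI graph ({len(seeds)} seeds missing)")

    if config.mode == "induced":
        admitted = found
    elif config.mode == "induced_plus_bridges":
        adj = ppi.adjacency()
        bridges = {
            v for v in ppi.nodes - seeds if len(adj[v] & found) >= 2
        }
        admitted = found | bridges
    else:  # first_neighbors
        adj = ppi.adjacency()
        admitted = set(found)
        for s in found:
            admitted |= adj[s]

    edges = frozenset(e for e in ppi.edges if e[0] in admitted and e[1] in admitted)
    return PPIGraph(nodes=frozenset(admitted), edges=edges)


def merge_networks(
    g1: PPIGraph, g2: PPIGraph, config: MergeConfig | None = None
) -> PPIGraph:
    """Merge two seed networks into one (the CPPI under the default mode)."""
    config = config or MergeConfig()
    if config.mode == "union":
        return PPIGraph(nodes=g1.nodes | g2.nodes, edges=g1.edges | g2.edges)
    nodes = g1.nodes & g2.nodes
    if not nodes:
        warnings.warn("node intersection of the two networks is empty", stacklevel=2)
        return PPIGraph(nodes=frozenset(), edges=frozenset())
    edges = frozenset(
        e for e in (g1.edges | g2.edges) if e[0] in nodes and e[1] in nodes
    )
    return PPIGraph(nodes=nodes, edges=edges)
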