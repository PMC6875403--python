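from __future__ import annotations

import networkx as nx
import pytest

from netpharm.ppi import PPIGraph, build_graph
from netpharm.screen import CompoundRecord


def nx_to_ppi(g: nx.Graph) -> PPIGraph:
    relabeled = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes()})
    return PPIGraph.from_networkx(relabeled)


@pytest.fixture(scope="session")
def small_graph_library() -> list[PPIGraph]:
    """>= 50 random connected graphs on <= 7 nodes plus named small graphs.

    The substrate for exhaustive centrality-oracle comparisons.
    """
    graphs: list[nx.Graph] = [
        nx.complete_graph(3),           # triangle
        nx.path_graph(3),
        nx.path_graph(5),
        nx.star_graph(4),               # star with 4 leaves
        nx.cycle_graph(5),
        nx.complete_graph(4),
        nx.complete_graph(5),
        nx.complete_bipartite_graph(2, 3),
        nx.wheel_graph(6),
        nx.lollipop_graph(4, 2),
        nx.bull_graph(),
        nx.house_graph(),
        nx.diamond_graph(),
    ]
    made = 0
    seed = 0
    while made < 55:
        seed += 1
        rng_n = 4 + seed % 4  # 4..7 nodes
        g = nx.gnp_random_graph(rng_n, 0.5, seed=seed)
        if nx.is_connected(g) and g.number_of_edges() > 0:
            graphs.append(g)
            made += 1
    return [nx_to_ppi(g) for g in graphs]


@pytest.fixture()
def triangle() -> PPIGraph:
    return build_graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture()
def path3() -> PPIGraph:
    return build_graph([("A", "B"), ("B", "C")])


@pytest.fixture()
def star4() -> PPIGraph:
    return build_graph([("HUB", f"L{i}") for i in range(1, 5)])


def make_compound(cid="C1", name="cpd", herbs=("BGZ",), ob=50.0, dl=0.5, wl=False):
    return CompoundRecord(
        compound_id=cid, name=name, herbs=frozenset(herbs), ob=ob, dl=dl, whitelisted=wl
    )


@pytest.fixture()
def synthetic_bundle(tmp_path):
    """Default synthetic input bundle written to a temp dir, with manifest."""
    from netpharm.synth import SyntheticSpec, gen_all

    spec = SyntheticSpec(seed=11)
    manifest = gen_all(spec, tmp_path / "bundle")
    return tmp_path / "bundle", manifest, spec
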