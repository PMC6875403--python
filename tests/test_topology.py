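import math

import numpy as np
import pytest

from netpharm.ppi import build_graph
from netpharm.topology import (
    CentralityRecord,
    HubThresholds,
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    local_average_connectivity,
    median_thresholds,
    network_centrality,
    select_hubs,
)

import _oracles as bf


class TestDegree:
    def test_triangle_all_two(self, triangle):
        assert set(degree_centrality(triangle).values()) == {2}

    def test_star(self, star4):
        dc = degree_centrality(star4)
        assert dc["HUB"] == 4 and dc["L1"] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        g = build_graph(
            [(f"P{int(rng.integers(30))}", f"P{int(rng.integers(30))}") for _ in range(120)]
        )
        assert sum(degree_centrality(g).values()) == 2 * g.n_edges


class TestBetweenness:
    def test_path_middle_mediates_one_pair(self, path3):
        bc = betweenness_centrality(path3)
        assert bc["B"] == pytest.approx(1.0)
        assert bc["A"] == bc["C"] == 0.0

    def test_star_center_mediates_all_leaf_pairs(self, star4):
        assert betweenness_centrality(star4)["HUB"] == pytest.approx(math.comb(4, 2))

    def test_disconnected_pairs_contribute_zero(self):
        g = build_graph([("A", "B"), ("B", "C"), ("X", "Y")])
        bc = betweenness_centrality(g)
        assert bc["B"] == pytest.approx(1.0)
        assert bc["X"] == bc["Y"] == 0.0


class TestCloseness:
    def test_triangle_complete(self, triangle):
        assert set(closeness_centrality(triangle).values()) == {1.0}

    def test_path_distance_sums(self, path3):
        cc = closeness_centrality(path3)
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)

    def test_component_local(self):
        g = build_graph(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")]
        )
        assert set(closeness_centrality(g).values()) == {1.0}

    def test_cc_is_one_iff_adjacent_to_whole_component(self, star4):
        cc = closeness_centrality(star4)
        assert cc["HUB"] == pytest.approx(1.0)
        assert all(v < 1 for k, v in cc.items() if k != "HUB")


class TestEigenvector:
    def test_triangle_symmetric(self, triangle):
        ec = eigenvector_centrality(triangle)
        for v in ec.values():
            assert v == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_regular_graph_uniform(self):
        g = build_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])  # C4
        vals = list(eigenvector_centrality(g).values())
        assert max(vals) - min(vals) < 1e-9

    def test_edgeless_graph_warns_zero(self):
        from netpharm.ppi import PPIGraph

        g = PPIGraph(nodes=frozenset({"A", "B"}), edges=frozenset())
        with pytest.warns(UserWarning):
            ec = eigenvector_centrality(g)
        assert set(ec.values()) == {0.0}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_eigen_equation_residual(self, seed):
        rng = np.random.default_rng(seed)
        g = build_graph(
            [(f"P{int(rng.integers(15))}", f"P{int(rng.integers(15))}") for _ in range(40)]
        )
        ec = eigenvector_centrality(g)
        _, lam = bf.bf_eigenvector(g.nodes, g.edges)
        adj = g.adjacency()
        for v in g.nodes:
            lhs = sum(ec[u] for u in adj[v])
            assert lhs == pytest.approx(lam * ec[v], abs=1e-8)


class TestNCandLAC:
    def test_triangle_values(self, triangle):
        assert set(network_centrality(triangle).values()) == {2.0}
        assert set(local_average_connectivity(triangle).values()) == {1.0}

    def test_star_all_zero(self, star4):
        assert set(network_centrality(star4).values()) == {0.0}
        assert local_average_connectivity(star4)["HUB"] == 0.0


class TestOracleSuite:
    """All six centralities vs exhaustive brute force on the graph library."""

    def test_all_centralities_match_brute_force(self, small_graph_library):
        assert len(small_graph_library) >= 50
        for g in small_graph_library:
            nodes, edges = g.nodes, g.edges
            dc = degree_centrality(g)
            adj = bf.adjacency(nodes, edges)
            for v in nodes:
                assert dc[v] == len(adj[v])
            bc = betweenness_centrality(g)
            bc_ref = bf.bf_betweenness(nodes, edges)
            cc = closeness_centrality(g)
            cc_ref = bf.bf_closeness(nodes, edges)
            nc = network_centrality(g)
            nc_ref = bf.bf_network_centrality(nodes, edges)
            lac = local_average_connectivity(g)
            lac_ref = bf.bf_lac(nodes, edges)
            for v in nodes:
                assert bc[v] == pytest.approx(bc_ref[v], abs=1e-9)
                assert cc[v] == pytest.approx(cc_ref[v], abs=1e-12)
                assert nc[v] == pytest.approx(nc_ref[v], abs=1e-12)
                assert lac[v] == pytest.approx(lac_ref[v], abs=1e-12)
            ec = eigenvector_centrality(g)
            ec_ref, lam = bf.bf_eigenvector(nodes, edges)
            for v in nodes:
                lhs = sum(ec[u] for u in adj[v])
                assert lhs == pytest.approx(lam * ec[v], abs=1e-8)
            assert np.linalg.norm(list(ec.values())) == pytest.approx(1.0, abs=1e-9)

    def test_label_equivariance(self, small_graph_library):
        """Permuting node labels permutes all outputs identically."""
        g = small_graph_library[10]
        mapping = {v: f"Z{i}" for i, v in enumerate(sorted(g.nodes, reverse=True))}
        g2 = build_graph([(mapping[u], mapping[v]) for u, v in g.edges])
        t1 = {r.node: r for r in centrality_table(g)}
        t2 = {r.node: r for r in centrality_table(g2)}
        for v in g.nodes:
            if mapping[v] not in t2:  # isolated nodes vanish under rebuild
                continue
            a, b = t1[v], t2[mapping[v]]
            assert a.values() == pytest.approx(b.values(), abs=1e-9)


def random_table(rng, n, with_ties=False):
    rows = []
    for i in range(n):
        dc = int(rng.integers(0, 10))
        vals = rng.random(5)
        if with_ties and rng.random() < 0.5:
            vals = np.round(vals, 1)
        rows.append(
            CentralityRecord(
                node=f"N{i}", dc=dc, bc=float(vals[0]) * 10, cc=float(vals[1]),
                ec=float(vals[2]), nc=float(vals[3]) * 5, lac=float(vals[4]) * 3,
            )
        )
    return rows


class TestMediansAndHubs:
    def test_single_node_thresholds(self):
        rec = CentralityRecord("A", 3, 1.0, 0.5, 0.2, 1.5, 0.7)
        thr = median_thresholds([rec])
        assert thr.values() == pytest.approx((3, 1.0, 0.5, 0.2, 1.5, 0.7))

    def test_even_count_midpoint_rule(self):
        rows = [CentralityRecord(f"N{i}", dc, 0, 0.5, 0, 0, 0) for i, dc in enumerate([1, 2, 2, 1])]
        assert median_thresholds(rows).dc_med == pytest.approx(1.5)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            median_thresholds([])

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(12)
        rows = random_table(rng, 31)
        thr = median_thresholds(rows)
        for i, name in enumerate(["dc_med", "bc_med", "cc_med", "ec_med", "nc_med", "lac_med"]):
            vals = sorted(r.values()[i] for r in rows)
            assert getattr(thr, name) == pytest.approx(vals[len(vals) // 2])

    def test_identical_metric_yields_no_hubs(self):
        rows = [CentralityRecord(f"N{i}", 5, float(i), 0.5, float(i), float(i), float(i)) for i in range(6)]
        thr = median_thresholds(rows)
        assert select_hubs(rows, thr) == []

    def test_dominating_node_selected(self):
        rows = random_table(np.random.default_rng(13), 10)
        top = CentralityRecord("TOP", 99, 99.0, 1.0, 99.0, 99.0, 99.0)
        rows.append(top)
        rows.append(CentralityRecord("PAD", 0, 0.0, 0.0, 0.0, 0.0, 0.0))  # even size
        thr = median_thresholds(rows)
        assert "TOP" in select_hubs(rows, thr)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_brute_conjunction_and_bound(self, seed, with_ties):
        rng = np.random.default_rng(seed)
        rows = random_table(rng, int(rng.integers(2, 60)), with_ties)
        thr = median_thresholds(rows)
        hubs = select_hubs(rows, thr)
        t = thr.values()
        expected = sorted(
            r.node for r in rows if all(x > m for x, m in zip(r.values(), t))
        )
        assert hubs == expected
        assert len(hubs) <= len(rows) // 2

    def test_inclusive_rule_supersets_strict(self):
        rows = random_table(np.random.default_rng(14), 20, with_ties=True)
        thr_strict = median_thresholds(rows)
        thr_incl = HubThresholds(*thr_strict.values(), strict=False)
        assert set(select_hubs(rows, thr_strict)) <= set(select_hubs(rows, thr_incl))
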