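"""Weighted PPI construction, greedy module search, normalization,
selection, and enrichment statistics."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from pgnet import netmod
from pgnet.netmod import Module, SearchParams


def greedy_oracle(G, seed, d=2, r=0.1, max_size=50):
    """Independent step-by-step reimplementation of the growth rule.

    Candidates within distance <= d of the module; distance-d additions
    carry the interior nodes of a deterministic shortest path (BFS with
    sorted neighbor expansion); accept the Zm-maximizing addition iff
    Zm_new > Zm_old * (1 + r); ties by candidate name.
    """

    def zm(nodes):
        return sum(G.nodes[v]["z"] for v in nodes) / math.sqrt(len(nodes))

    module = {seed}
    score = zm(module)
    while len(module) < max_size:
        # multi-source BFS with parents, deterministic order
        depth = {v: 0 for v in module}
        parent = {}
        frontier = sorted(module)
        for dist in range(1, d + 1):
            nxt = []
            for u in frontier:
                for w in sorted(G.neighbors(u)):
                    if w not in depth:
                        depth[w] = dist
                        parent[w] = u
                        nxt.append(w)
            frontier = nxt
        best = None
        for v in sorted(set(depth) - module):
            interior = []
            u = parent[v]
            while depth[u] > 0:
                interior.append(u)
                u = parent[u]
            cand = module | {v} | set(interior)
            s = zm(cand)
            if best is None or s > best[0] + 1e-15:
                best = (s, v, cand)
        if best is None or not (best[0] > score * (1 + r)):
            break
        score, module = best[0], best[2]
    return module, score


def random_weighted_graph(rng, n_max=8):
    n = int(rng.integers(2, n_max + 1))
    while True:
        G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31)))
        if G.number_of_edges() > 0:
            break
    G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
    for v in G.nodes:
        G.nodes[v]["z"] = float(rng.normal())
    return G


class TestBuild:
    def test_dedup_and_self_loop_drop(self):
        G = netmod.build_weighted_ppi([("a", "b"), ("b", "a"), ("a", "a")], {})
        assert G.number_of_edges() == 1
        assert not any(u == v for u, v in G.edges)

    def test_unscored_node_gets_conservative_minimum(self):
        G = netmod.build_weighted_ppi([("a", "b")], {"a": 2.0})
        assert G.nodes["b"]["z"] == netmod.Z_MIN

    def test_weights_roundtrip_through_edge_writer(self, tmp_path):
        from pgnet import io

        G = netmod.build_weighted_ppi([("a", "b"), ("b", "c")], {"a": 1.2345678901234})
        io.write_edge_list(G, tmp_path / "e.tsv")
        edges = io.read_edge_list(tmp_path / "e.tsv")
        G2 = netmod.build_weighted_ppi(edges, {"a": 1.2345678901234})
        assert G2.nodes["a"]["z"] == G.nodes["a"]["z"]
        assert set(map(frozenset, G2.edges)) == set(map(frozenset, G.edges))

    def test_malformed_edge_line_reports_line_number(self, tmp_path):
        from pgnet import io

        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\nonlyone\n")
        with pytest.raises(ValueError, match="line 2"):
            io.read_edge_list(path)


class TestGrowth:
    def test_star_center_stays_alone(self):
        """Center z=3, leaves 0: any addition divides Zm by sqrt(2)."""
        edges = [("c", f"l{i}") for i in range(5)]
        G = netmod.build_weighted_ppi(edges, {"c": 3.0, **{f"l{i}": 0.0 for i in range(5)}})
        m = netmod.grow_module(G, "c", SearchParams(d=2, r=0.1))
        assert m.nodes == frozenset({"c"})
        assert m.zm == pytest.approx(3.0)

    def test_path_distance_two_admission_matches_oracle(self):
        """a-b-c with z=(2,0,2): c admissible at d=2 from seed a."""
        G = netmod.build_weighted_ppi([("a", "b"), ("b", "c")],
                                      {"a": 2.0, "b": 0.0, "c": 2.0})
        m = netmod.grow_module(G, "a", SearchParams(d=2, r=0.1))
        nodes, score = greedy_oracle(G, "a", d=2, r=0.1)
        assert set(m.nodes) == nodes
        assert m.zm == pytest.approx(score, abs=1e-12)
        # interior node b is carried along with c and counts toward k
        assert m.nodes == frozenset({"a", "b", "c"})
        assert m.zm == pytest.approx(4 / math.sqrt(3))

    def test_equal_weights_growth_stops_by_size_bound(self):
        """All z equal > 0: Zm = z*sqrt(k), growth factor < 1.1 for k >= 5."""
        G = nx.complete_graph(12)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G.nodes})
        for v in G.nodes:
            G.nodes[v]["z"] = 1.0
        m = netmod.grow_module(G, "n00", SearchParams(d=1, r=0.1))
        # sqrt((k+1)/k) > 1.1 requires k <= 4, so growth stops at k=5
        assert m.k == 5
        assert m.zm == pytest.approx(math.sqrt(5))

    def test_fuzz_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            G = random_weighted_graph(rng)
            seed = sorted(G.nodes)[int(rng.integers(0, G.number_of_nodes()))]
            m = netmod.grow_module(G, seed, SearchParams(d=2, r=0.1))
            nodes, score = greedy_oracle(G, seed)
            assert set(m.nodes) == nodes
            assert m.zm == pytest.approx(score, abs=1e-12)

    def test_every_module_satisfies_stopping_criterion(self):
        rng = np.random.default_rng(77)
        G = random_weighted_graph(rng, n_max=8)
        params = SearchParams(d=2, r=0.1)
        for m in netmod.dense_module_search(G, params):
            assert netmod.satisfies_stopping(G, m, params)

    def test_zm_reconstructible_from_weights(self):
        rng = np.random.default_rng(5)
        G = random_weighted_graph(rng)
        for m in netmod.dense_module_search(G, SearchParams(d=2, r=0.1)):
            assert abs(m.zm - netmod.module_score(G, m.nodes)) < 1e-12


class TestNormalization:
    def _graph(self, rng, n=60):
        G = nx.barabasi_albert_graph(n, 2, seed=3)
        G = nx.relabel_nodes(G, {i: f"n{i:03d}" for i in G.nodes})
        for v in G.nodes:
            G.nodes[v]["z"] = float(rng.normal())
        return G

    def test_equal_weights_zn_near_zero(self):
        G = nx.path_graph(30)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G.nodes})
        for v in G.nodes:
            G.nodes[v]["z"] = 1.0
        mods = [Module(seed="n00", nodes=frozenset(["n00", "n01", "n02"]), zm=3 / math.sqrt(3))]
        with pytest.raises(ValueError):  # all-equal weights: sd_k = 0
            netmod.normalize_modules(mods, G, b_norm=1000, seed=0)

    def test_planted_high_z_module_exceeds_random_sets(self):
        rng = np.random.default_rng(9)
        G = self._graph(rng)
        planted = sorted(G.nodes)[:6]
        for v in planted:
            G.nodes[v]["z"] = 4.0
        mods = [Module(seed=planted[0], nodes=frozenset(planted),
                       zm=netmod.module_score(G, planted))]
        out = netmod.normalize_modules(mods, G, b_norm=10_000, seed=1)
        assert out[0].zn > stats.norm.isf(0.01)  # beyond the 99th percentile

    def test_same_seed_identical_zn(self):
        rng = np.random.default_rng(10)
        G = self._graph(rng)
        mods = netmod.dense_module_search(G, SearchParams(d=2, r=0.1),
                                          seed_nodes=sorted(G.nodes)[:10])
        a = netmod.normalize_modules(mods, G, b_norm=500, seed=4)
        b = netmod.normalize_modules(mods, G, b_norm=500, seed=4)
        assert [m.zn for m in a] == [m.zn for m in b]


class TestSelection:
    def _mods(self, n):
        return [
            Module(seed=f"s{i:05d}", nodes=frozenset([f"s{i:05d}"]), zm=float(i),
                   zn=float(i))
            for i in range(n)
        ]

    def test_ceiling_count_on_paper_scale(self):
        sel, _ = netmod.top_percent_modules(self._mods(13_897), q=0.01)
        assert len(sel) == 139

    def test_q_one_selects_all(self):
        sel, _ = netmod.top_percent_modules(self._mods(10), q=1.0)
        assert len(sel) == 10

    def test_tie_break_deterministic(self):
        mods = [
            Module(seed="b", nodes=frozenset("b"), zm=1.0, zn=1.0),
            Module(seed="a", nodes=frozenset("a"), zm=1.0, zn=1.0),
            Module(seed="c", nodes=frozenset("c"), zm=2.0, zn=1.0),
        ]
        sel, _ = netmod.top_percent_modules(mods, q=0.5)
        assert [m.seed for m in sel] == ["c", "a"]


class TestOverlap:
    def test_paper_scale_fisher(self):
        a = {f"p{i}" for i in range(577)}
        b = {f"p{i}" for i in range(563, 563 + 175)}  # overlap 14
        ov, p, odds = netmod.overlap_test(a, b, 16_420)
        assert ov == 14
        assert abs(p - 0.003) <= 0.001

    def test_no_overlap_p_one(self):
        ov, p, _ = netmod.overlap_test({"a"}, {"b"}, 4)
        assert ov == 0 and p == pytest.approx(1.0)

    def test_balanced_table_matches_enumeration(self):
        """Overlap 1 of 2x2 sets in universe 4: brute-force tail sum."""
        ov, p, _ = netmod.overlap_test({"a", "b"}, {"b", "c"}, 4)
        # X ~ Hypergeom(N=4, K=2, n=2): P(X >= 1) = 1 - P(0) = 1 - 1/6
        assert ov == 1
        assert p == pytest.approx(1 - 1 / math.comb(4, 2))

    def test_complete_overlap_minimal_p(self):
        a = {"x", "y"}
        ov, p, _ = netmod.overlap_test(a, a, 10)
        # point mass of the maximal table: C(2,2)*C(8,0)/C(10,2)
        assert ov == 2
        assert p == pytest.approx(1 / math.comb(10, 2))

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            netmod.overlap_test({"a", "b"}, {"a"}, 1)


class TestFirstDegree:
    def test_star_center_returns_whole_star(self):
        edges = [("c", f"l{i}") for i in range(4)]
        G = netmod.build_weighted_ppi(edges, {})
        sub = netmod.first_degree_network(G, {"c"})
        assert set(sub.nodes) == {"c", "l0", "l1", "l2", "l3"}

    def test_isolated_risk_node(self):
        G = netmod.build_weighted_ppi([("a", "b")], {})
        G.add_node("iso")
        sub = netmod.first_degree_network(G, {"iso"})
        assert set(sub.nodes) == {"iso"}

    def test_shared_neighbor_not_duplicated(self):
        G = netmod.build_weighted_ppi([("r1", "n"), ("r2", "n")], {})
        sub = netmod.first_degree_network(G, {"r1", "r2"})
        assert sorted(sub.nodes) == ["n", "r1", "r2"]

    def test_absent_loci_error(self):
        G = netmod.build_weighted_ppi([("a", "b")], {})
        with pytest.raises(ValueError):
            netmod.first_degree_network(G, {"zzz"})


class TestPermutation:
    def _graph(self, n=100):
        G = nx.path_graph(n)
        return nx.relabel_nodes(G, {i: f"n{i:03d}" for i in G.nodes})

    def test_pqtl_equals_universe_p_one(self):
        G = self._graph()
        nodes = set(G.nodes)
        p_emp, _ = netmod.permutation_enrichment(G, set(list(nodes)[:10]), nodes,
                                                 B=500, seed=0)
        assert p_emp == 1.0

    def test_plus_one_convention_floor(self):
        """Observed overlap beats every permutation -> p = 1/(B+1)."""
        G = self._graph(400)
        nodes = sorted(G.nodes)
        neighbor = set(nodes[:8])
        pqtl = set(nodes[:8])  # perfect overlap 8/8, K=8 of 400
        p_emp, p_obs = netmod.permutation_enrichment(G, neighbor, pqtl,
                                                     B=10_000, seed=1)
        assert p_emp == pytest.approx(1 / 10_001)

    def test_relabeling_invariance(self):
        G = self._graph(60)
        nodes = sorted(G.nodes)
        neighbor, pqtl = set(nodes[5:20]), set(nodes[10:30])
        p1, _ = netmod.permutation_enrichment(G, neighbor, pqtl, B=2000, seed=3)
        mapping = {v: f"x{v}" for v in nodes}
        H = nx.relabel_nodes(G, mapping)
        p2, _ = netmod.permutation_enrichment(
            H, {mapping[v] for v in neighbor}, {mapping[v] for v in pqtl},
            B=2000, seed=3,
        )
        assert p1 == p2
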