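"""Local modularity score, greedy expansion, and module discovery."""

import itertools

import networkx as nx
import numpy as np
import pytest

from smokenet.modules import SearchConfig, find_modules, greedy_expand, local_modularity


def _random_weighted_graph(n, p, seed, low=0.05, high=1.0):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(low, high))
    for node in g.nodes:
        g.nodes[node]["adjusted_p"] = float(rng.uniform(0.001, 1.0))
        g.nodes[node]["neg_log10_p"] = -np.log10(g.nodes[node]["adjusted_p"])
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


def _oracle_score(g, members, gamma):
    w_in = sum(d["weight"] ** gamma for u, v, d in g.edges(data=True)
               if u in members and v in members)
    w_bnd = sum(d["weight"] ** gamma for u, v, d in g.edges(data=True)
                if (u in members) != (v in members))
    return w_in / (w_in + w_bnd)


class TestLocalModularity:
    def test_whole_component_scores_one(self, toy_weighted_network):
        g = toy_weighted_network
        assert local_modularity(g, set(g.nodes)) == pytest.approx(1.0)

    def test_triangle_with_one_leaving_edge(self):
        g = nx.Graph()
        for a, b in [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]:
            g.add_edge(a, b, weight=1.0)
        assert local_modularity(g, {"A", "B", "C"}) == pytest.approx(0.75)

    def test_gamma_zero_reduces_to_edge_counts(self):
        for seed in range(5):
            g = _random_weighted_graph(12, 0.35, seed)
            nodes = sorted(g.nodes)
            rng = np.random.default_rng(seed)
            for _ in range(10):
                members = set(rng.choice(nodes, size=rng.integers(2, 8), replace=False))
                sub = g.subgraph(members)
                if not members or not nx.is_connected(sub):
                    continue
                n_in = sub.number_of_edges()
                n_bnd = sum(1 for u, v in g.edges(members) if (u in members) != (v in members))
                if n_in + n_bnd == 0:
                    continue
                assert local_modularity(g, members, gamma=0.0) == pytest.approx(
                    n_in / (n_in + n_bnd))

    def test_monotone_under_internal_edge_addition(self):
        g = _random_weighted_graph(10, 0.4, 3)
        members = set(sorted(g.nodes)[:5])
        if not nx.is_connected(g.subgraph(members)):
            pytest.skip("fixture subgraph disconnected")
        before = local_modularity(g, members)
        inside = [e for e in itertools.combinations(sorted(members), 2) if not g.has_edge(*e)]
        if not inside:
            pytest.skip("members already a clique")
        g.add_edge(*inside[0], weight=0.5)
        assert local_modularity(g, members) >= before - 1e-12

    def test_disconnected_members_rejected(self, toy_weighted_network):
        with pytest.raises(ValueError, match="connected"):
            local_modularity(toy_weighted_network, {"A", "F"})

    def test_matches_direct_oracle(self):
        for seed in range(5):
            g = _random_weighted_graph(10, 0.45, seed)
            nodes = sorted(g.nodes)
            members = set(nodes[:4])
            if not nx.is_connected(g.subgraph(members)):
                continue
            for gamma in (0.5, 1.0, 2.0):
                assert local_modularity(g, members, gamma) == pytest.approx(
                    _oracle_score(g, members, gamma))


class TestGreedyExpand:
    def test_deterministic(self, toy_weighted_network):
        cfg = SearchConfig(size_min=3, n_null=100)
        a = greedy_expand(toy_weighted_network, ("A", "B"), cfg)
        b = greedy_expand(toy_weighted_network, ("A", "B"), cfg)
        assert a.members == b.members and a.score == b.score

    def test_recovers_heavy_triangle(self, toy_weighted_network):
        cfg = SearchConfig(size_min=3, size_max=4, n_null=100)
        sub = greedy_expand(toy_weighted_network, ("A", "B"), cfg)
        assert {"A", "B", "C"} <= sub.members

    def test_returns_none_below_size_min(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=0.001)
        for n in g.nodes:
            g.nodes[n]["adjusted_p"] = 0.5
        cfg = SearchConfig(size_min=5, n_null=100)
        assert greedy_expand(g, ("A", "B"), cfg) is None

    def test_terminal_score_bounded_by_exhaustive_optimum(self):
        # on graphs <= 10 nodes, greedy cannot beat the best connected
        # superset of its seed edge at terminal size
        for seed in range(4):
            g = _random_weighted_graph(9, 0.45, seed)
            edges = sorted(tuple(sorted(e)) for e in g.edges)
            if not edges:
                continue
            seed_edge = edges[0]
            cfg = SearchConfig(size_min=3, size_max=9, n_null=100)
            sub = greedy_expand(g, seed_edge, cfg)
            if sub is None:
                continue
            nodes = sorted(g.nodes)
            best = 0.0
            for k in range(2, 10):
                for combo in itertools.combinations(nodes, k):
                    members = set(combo)
                    if not set(seed_edge) <= members:
                        continue
                    if not nx.is_connected(g.subgraph(members)):
                        continue
                    best = max(best, _oracle_score(g, members, cfg.gamma))
            assert sub.score <= best + 1e-9


class TestFindModules:
    def _planted_network(self, seed=0):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(60, 0.08, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.05
        clique = [f"C{i}" for i in range(6)]
        for a, b in itertools.combinations(clique, 2):
            g.add_edge(a, b, weight=0.95)
        hubs = sorted(g.nodes, key=g.degree, reverse=True)[:6]
        for c, h in zip(clique, hubs):
            g.add_edge(c, h, weight=0.1)
        for n in g.nodes:
            # graded background significance keeps bulk edge weights away
            # from zero, so boundary neighbors are not engulfed for free
            g.nodes[n]["adjusted_p"] = float(rng.uniform(0.05, 0.5))
            g.nodes[n]["neg_log10_p"] = -np.log10(g.nodes[n]["adjusted_p"])
        for n in clique:
            g.nodes[n]["adjusted_p"] = 1e-6
            g.nodes[n]["neg_log10_p"] = 6.0
        g.graph["log_p_min"] = float(np.log(1e-6))
        g.remove_nodes_from(list(nx.isolates(g)))
        return g, set(clique)

    def test_recovers_planted_clique(self):
        g, clique = self._planted_network()
        cfg = SearchConfig(size_min=5, n_null=100, max_seeds=20, seed=0)
        found = find_modules(g, cfg)
        assert found, "planted clique not detected"
        best = max(found, key=lambda m: len(m.members & clique))
        jac = len(best.members & clique) / len(best.members | clique)
        assert jac >= 0.8 and best.empirical_p <= 0.05

    def test_empirical_p_respects_add_one_bound(self):
        g, _ = self._planted_network()
        cfg = SearchConfig(size_min=5, n_null=100, max_seeds=20, seed=0)
        for m in find_modules(g, cfg):
            assert m.empirical_p >= 1 / (1 + cfg.n_null)

    def test_invariant_to_node_insertion_order(self):
        g1, _ = self._planted_network()
        g2 = nx.Graph(log_p_min=g1.graph["log_p_min"])
        for u, v, d in sorted(g1.edges(data=True), reverse=True):
            g2.add_edge(u, v, **d)
        for n, d in g1.nodes(data=True):
            g2.nodes[n].update(d)
        cfg = SearchConfig(size_min=5, n_null=100, max_seeds=20, seed=0)
        a = find_modules(g1, cfg)
        b = find_modules(g2, cfg)
        assert [m.members for m in a] == [m.members for m in b]
        assert [m.empirical_p for m in a] == [m.empirical_p for m in b]

    def test_tiny_network_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        with pytest.raises(ValueError):
            find_modules(g, SearchConfig(size_min=5, n_null=100))

    def test_accepted_modules_respect_overlap_cap(self):
        g, _ = self._planted_network()
        cfg = SearchConfig(size_min=5, n_null=100, max_seeds=20, seed=0,
                           overlap_jaccard_max=0.5)
        found = find_modules(g, cfg)
        for a, b in itertools.combinations(found, 2):
            jac = len(a.members & b.members) / len(a.members | b.members)
            assert jac <= 0.5
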