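"""Edge costs, prizes, the PCSF solver and supernode augmentation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from shapenet.assembly import (
    PCSFParams,
    add_supernodes,
    assemble_network,
    collect_prizes,
    edge_costs,
    network_stats,
    pcsf_objective,
    pcsf_solve,
    pcsf_union,
    prior_digraph,
    undirected_view,
)
from shapenet.coexpression import ModuleShapeCorrelation


def _prior(rows):
    return pd.DataFrame(rows, columns=["source", "target", "sign",
                                       "n_sources"])


def pcsf_oracle(graph: nx.Graph, prizes: dict, w: float) -> float:
    """Exhaustive optimum: enumerate node subsets; each subset's cheapest
    forest is the MST of the induced subgraph plus a virtual root joined to
    every chosen node at cost w (the MST picks the optimal tree count)."""
    nodes = sorted(set(graph) | set(prizes))
    best = sum(prizes.values())
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            s = set(subset)
            aug = nx.Graph()
            aug.add_nodes_from(s)
            for a, b, d in graph.subgraph(s).edges(data=True):
                aug.add_edge(a, b, weight=d["cost"])
            for v in s:
                aug.add_edge("__R__", v, weight=w)
            mst = nx.minimum_spanning_tree(aug, weight="weight")
            cost = sum(d["weight"] for *_, d in mst.edges(data=True))
            missed = sum(p for v, p in prizes.items() if v not in s)
            best = min(best, cost + missed)
    return best


class TestEdgeCosts:
    def test_extremes_of_the_scaling(self):
        prior = _prior([("a", "b", 1, 25), ("b", "c", 1, 1),
                        ("c", "d", -1, 5)])
        costs = edge_costs(prior)
        assert costs.iloc[0] == 0.0  # max sources
        assert costs.iloc[1] == 1.0  # global min

    def test_worked_three_count_case(self):
        prior = _prior([("a", "b", 1, 1), ("b", "c", 1, 2),
                        ("c", "d", 1, 4)])
        costs = edge_costs(prior)
        assert costs.tolist() == pytest.approx([1.0, 1 / 3, 0.0])

    def test_equal_counts_give_half(self):
        prior = _prior([("a", "b", 1, 3), ("b", "c", 1, 3)])
        assert (edge_costs(prior) == 0.5).all()

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            edge_costs(_prior([("a", "a", 1, 1)]))


class TestCollectPrizes:
    def test_mu_zero_gives_raw_prize(self):
        g = nx.Graph([("a", "b")])
        prizes = collect_prizes({"a"}, set(), set(), PCSFParams(mu=0.0), g)
        assert prizes == {"a": 100.0}

    def test_hub_penalty_floors_at_zero(self):
        g = nx.Graph([("hub", f"n{i}") for i in range(30)])
        params = PCSFParams(mu=5.0)  # 5 * 30 = 150 > 100
        prizes = collect_prizes({"hub"}, set(), set(), params, g)
        assert prizes["hub"] == 0.0

    def test_absent_node_kept_with_degree_zero(self):
        g = nx.Graph([("a", "b")])
        prizes = collect_prizes({"ghost"}, set(), set(), PCSFParams(), g)
        assert prizes["ghost"] == 100.0

    def test_empty_inputs_give_empty_map(self):
        assert collect_prizes(set(), set(), set(), PCSFParams(),
                              nx.Graph()) == {}


class TestPCSFSolve:
    def test_worked_path_instance_selects_both_edges(self):
        g = nx.Graph()
        g.add_edge("A", "B", cost=1.0)
        g.add_edge("B", "C", cost=1.0)
        sol = pcsf_solve(g, {"A": 100.0, "C": 100.0}, PCSFParams(w=40))
        assert set(sol.nodes()) == {"A", "B", "C"}
        assert sol.number_of_edges() == 2

    def test_cheap_prize_dropped(self):
        g = nx.Graph()
        g.add_edge("A", "B", cost=1.0)
        sol = pcsf_solve(g, {"A": 0.1}, PCSFParams(w=40))
        assert len(sol) == 0

    def test_single_valuable_prize_returned_alone(self):
        g = nx.Graph()
        g.add_edge("A", "B", cost=1.0)
        sol = pcsf_solve(g, {"A": 100.0}, PCSFParams(w=40))
        assert set(sol.nodes()) == {"A"}
        assert sol.number_of_edges() == 0

    def test_no_prizes_gives_empty_solution(self):
        g = nx.Graph()
        g.add_edge("A", "B", cost=0.1)
        assert len(pcsf_solve(g, {}, PCSFParams())) == 0

    def test_objective_never_worse_than_empty_solution(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1e6)))
            graph = nx.Graph()
            graph.add_nodes_from(g.nodes())
            for a, b in g.edges():
                graph.add_edge(a, b, cost=float(rng.uniform(0.05, 1)))
            prizes = {int(v): float(rng.uniform(0.1, 3))
                      for v in rng.choice(n, size=max(1, n // 3),
                                          replace=False)}
            params = PCSFParams(w=float(rng.uniform(0.1, 1.5)))
            sol = pcsf_solve(graph, prizes, params)
            assert (pcsf_objective(sol, prizes, params.w)
                    <= sum(prizes.values()) + 1e-12)

    def test_within_ten_percent_of_exhaustive_optimum(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(6, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1e6)))
            graph = nx.Graph()
            graph.add_nodes_from(g.nodes())
            for a, b in g.edges():
                graph.add_edge(a, b, cost=float(rng.uniform(0.05, 1)))
            k = int(rng.integers(2, max(3, n // 2)))
            prizes = {int(v): float(rng.uniform(0.2, 3))
                      for v in rng.choice(n, size=k, replace=False)}
            w = float(rng.uniform(0.1, 1.5))
            sol = pcsf_solve(graph, prizes, PCSFParams(w=w))
            obj = pcsf_objective(sol, prizes, w)
            opt = pcsf_oracle(graph, prizes, w)
            assert obj <= opt * 1.10 + 1e-9

    def test_exact_on_tree_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 12))
            t = nx.random_labeled_tree(n, seed=int(rng.integers(1e6)))
            graph = nx.Graph()
            for a, b in t.edges():
                graph.add_edge(a, b, cost=float(rng.uniform(0.05, 1)))
            prizes = {int(v): float(rng.uniform(0.2, 3))
                      for v in rng.choice(n, size=max(2, n // 2),
                                          replace=False)}
            w = float(rng.uniform(0.1, 1.5))
            sol = pcsf_solve(graph, prizes, PCSFParams(w=w))
            obj = pcsf_objective(sol, prizes, w)
            assert obj == pytest.approx(pcsf_oracle(graph, prizes, w),
                                        abs=1e-9)


class TestPCSFUnion:
    def _instance(self):
        g = nx.Graph()
        g.add_edge("A", "B", cost=0.5)
        g.add_edge("B", "C", cost=0.5)
        g.add_edge("A", "D", cost=0.51)
        g.add_edge("D", "C", cost=0.5)
        return g, {"A": 100.0, "C": 100.0}

    def test_zero_noise_equals_single_run(self):
        g, prizes = self._instance()
        params = PCSFParams(w=40, noise_frac=0.0, iterations=10, seed=3)
        union = pcsf_union(g, prizes, params)
        single = pcsf_solve(g, prizes, params)
        assert set(union.edges()) == set(single.edges())

    def test_union_contains_every_single_run(self):
        g, prizes = self._instance()
        params = PCSFParams(w=40, noise_frac=0.05, iterations=15, seed=4)
        union = pcsf_union(g, prizes, params)
        single = pcsf_solve(g, prizes, params)
        assert set(single.nodes()) <= set(union.nodes())

    def test_near_equal_paths_both_sampled(self):
        g, prizes = self._instance()
        params = PCSFParams(w=40, noise_frac=0.05, iterations=30, seed=5)
        union = pcsf_union(g, prizes, params)
        assert {"B", "D"} <= set(union.nodes())

    def test_deterministic_given_seed(self):
        g, prizes = self._instance()
        params = PCSFParams(w=40, noise_frac=0.05, iterations=10, seed=6)
        u1 = pcsf_union(g, prizes, params)
        u2 = pcsf_union(g, prizes, params)
        assert sorted(u1.edges()) == sorted(u2.edges())


class TestSupernodes:
    def _net(self):
        prior = _prior([("TF1", "g0", 1, 5), ("g0", "g1", 1, 3),
                        ("g1", "g2", -1, 2)])
        sol = undirected_view(prior_digraph(prior))
        return assemble_network(prior, sol)

    def _corr(self, r, p):
        df = pd.DataFrame({"feat": [r]}, index=["M1"])
        pdf = pd.DataFrame({"feat": [p]}, index=["M1"])
        return ModuleShapeCorrelation(df, pdf, pdf, None, None,
                                      (df.abs() > 0.5) & (pdf < 0.05))

    def test_enriched_tf_connected_to_supernode(self):
        net = self._net()
        universe = {f"g{i}" for i in range(20)}
        modules = {"M1": [f"g{i}" for i in range(5)]}
        regulons = {"TF1": {"activated": {"g0", "g1", "g2", "g3", "g4"},
                            "repressed": set(), "unknown": set()}}
        out = add_supernodes(net, modules, regulons, self._corr(0.9, 1e-4),
                             universe)
        assert out.has_edge("TF1", "GEM:M1")
        assert out.has_edge("GEM:M1", "PHENO:feat")
        # feedback to in-network members only, with weight exactly 1
        assert out.has_edge("GEM:M1", "g0")
        assert out["GEM:M1"]["g0"]["weight"] == 1.0
        assert not out.has_edge("GEM:M1", "g4")

    def test_weak_correlation_gets_no_phenotype_edge(self):
        net = self._net()
        modules = {"M1": ["g0", "g1"]}
        out = add_supernodes(net, modules, {}, self._corr(0.4, 1e-4),
                             {f"g{i}" for i in range(20)})
        assert "PHENO:feat" not in out


class TestNetworkStats:
    def test_star_center_has_top_betweenness(self):
        net = nx.DiGraph()
        for i in range(6):
            net.add_edge("hub", f"n{i}", weight=1.0)
        stats = network_stats(net)
        assert stats["betweenness"][0][0] == "hub"

    def test_path_middle_node_betweenness(self):
        net = nx.DiGraph()
        for a, b in zip("abcde", "bcdef"[:4]):
            net.add_edge(a, b, weight=1.0)
        stats = network_stats(net)
        betw = dict(stats["betweenness"])
        assert betw["c"] == 4.0  # pairs (a,d),(a,e),(b,d),(b,e)

    def test_full_prize_coverage(self):
        net = nx.DiGraph()
        net.add_edge("a", "b", weight=1.0)
        stats = network_stats(net, prizes={"a": 10.0, "b": 5.0})
        assert stats["prize_coverage"] == 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.DiGraph())
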