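"""Semantic similarity, RWR diffusion and shortest-path explanations."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from shapenet.propagation import (
    OntologyDAG,
    per_seed_decomposition,
    resnik_bma,
    resnik_pairwise,
    reweight_edges,
    rwr,
    seed_significance,
    shortest_path_subgraph,
    _transition_matrix,
)


def _chain_ontology():
    """root -> t1 -> t2 with three genes annotated at different depths."""
    parents = {"root": set(), "t1": {"root"}, "t2": {"t1"}}
    annotations = {"gA": {"t2"}, "gB": {"t2"}, "gC": {"t1"}, "gD": {"root"}}
    return OntologyDAG(parents, annotations)


class TestResnik:
    def test_root_only_genes_have_zero_similarity(self):
        onto = OntologyDAG({"root": set()}, {"a": {"root"}, "b": {"root"}})
        assert resnik_bma(onto, "a", "b") == 0.0

    def test_identical_single_annotation_returns_term_ic(self):
        onto = _chain_ontology()
        ic_t2 = onto.ic["t2"]  # 2 of 4 genes -> -ln(1/2)
        assert ic_t2 == pytest.approx(-np.log(0.5))
        assert resnik_bma(onto, "gA", "gB") == pytest.approx(ic_t2)

    def test_symmetry(self):
        onto = _chain_ontology()
        assert resnik_bma(onto, "gA", "gC") == resnik_bma(onto, "gC", "gA")

    def test_unannotated_gene_gives_zero(self):
        onto = _chain_ontology()
        assert resnik_bma(onto, "gA", "missing") == 0.0

    def test_matches_all_pairs_oracle_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            # random layered DAG
            parents = {"root": set()}
            terms = ["root"]
            for lvl in range(3):
                new = [f"t{lvl}_{i}" for i in range(4)]
                for t in new:
                    k = int(rng.integers(1, 3))
                    parents[t] = set(rng.choice(terms, size=min(k, len(terms)),
                                                replace=False))
                terms.extend(new)
            genes = {f"g{i}": set(rng.choice(terms[1:], size=2,
                                             replace=False))
                     for i in range(8)}
            onto = OntologyDAG(parents, genes)

            def oracle(ga, gb):
                ta, tb = sorted(genes[ga]), sorted(genes[gb])
                m = [[resnik_pairwise(onto, a, b) for b in tb] for a in ta]
                m = np.asarray(m)
                return 0.5 * (m.max(1).mean() + m.max(0).mean())

            for ga in ["g0", "g3"]:
                for gb in ["g1", "g5"]:
                    assert resnik_bma(onto, ga, gb) == pytest.approx(
                        oracle(ga, gb), abs=1e-12)


class TestReweight:
    def test_scaling_endpoints_and_sign(self):
        onto = _chain_ontology()
        net = nx.DiGraph()
        net.add_node("gA", kind="protein")
        net.add_node("gB", kind="protein")
        net.add_node("gD", kind="protein")
        net.add_edge("gA", "gB", sign=-1, weight=1.0, origin="pcsf")
        net.add_edge("gB", "gD", sign=1, weight=1.0, origin="pcsf")
        out = reweight_edges(net, onto)
        # gA-gB shares t2 (max similarity), gB-gD only root (min)
        assert out["gA"]["gB"]["weight"] == pytest.approx(-1.0)
        assert out["gB"]["gD"]["weight"] == pytest.approx(0.0)

    def test_supernode_edges_keep_unit_weight(self):
        onto = _chain_ontology()
        net = nx.DiGraph()
        net.add_node("gA", kind="protein")
        net.add_node("GEM:M1", kind="gem_supernode")
        net.add_edge("GEM:M1", "gA", sign=1, weight=1.0, origin="feedback")
        out = reweight_edges(net, onto)
        assert out["GEM:M1"]["gA"]["weight"] == 1.0
        assert out["GEM:M1"]["gA"]["similarity"] == 1.0


class TestRWR:
    def _random_net(self, n, rng):
        g = nx.gnp_random_graph(n, 0.3, directed=True,
                                seed=int(rng.integers(1e6)))
        net = nx.DiGraph()
        net.add_nodes_from(g.nodes())
        for a, b in g.edges():
            net.add_edge(a, b, weight=float(rng.uniform(-1, 1)))
        return net

    def test_isolated_seed_keeps_all_mass(self):
        net = nx.DiGraph()
        net.add_node("x")
        res = rwr(net, {"x": 1.0})
        assert res.probability["x"] == pytest.approx(1.0)

    def test_matches_closed_form_solve(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 21))
            net = self._random_net(n, rng)
            seeds = {int(v): float(rng.uniform(0.5, 2.0))
                     for v in rng.choice(n, size=max(1, n // 4),
                                         replace=False)}
            res = rwr(net, seeds, 0.95)
            nodes = sorted(net.nodes())
            W = _transition_matrix(net, nodes)
            s = np.zeros(n)
            tot = sum(seeds.values())
            for v, m in seeds.items():
                s[nodes.index(v)] = m / tot
            q = np.linalg.solve(np.eye(n) - 0.05 * W.T, s)
            q /= q.sum()
            assert np.abs(res.probability.to_numpy() - q).max() < 1e-8

    def test_mass_conserved(self):
        rng = np.random.default_rng(2)
        net = self._random_net(30, rng)
        res = rwr(net, {0: 1.0, 3: 2.0})
        assert res.probability.sum() == pytest.approx(1.0, abs=1e-12)
        assert (res.probability >= 0).all()

    def test_higher_restart_concentrates_mass_on_seeds(self):
        rng = np.random.default_rng(3)
        net = self._random_net(25, rng)
        seeds = {0: 1.0, 1: 1.0}
        masses = [
            rwr(net, seeds, r).probability[[0, 1]].sum()
            for r in (0.5, 0.7, 0.9, 0.95)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_negative_seed_mass_rejected(self):
        net = nx.DiGraph()
        net.add_edge("a", "b", weight=1.0)
        with pytest.raises(ValueError):
            rwr(net, {"a": -1.0})


class TestSeedSignificance:
    def _star_net(self, n_leaves=10, n_background=200):
        net = nx.DiGraph()
        for i in range(n_leaves):
            net.add_edge(f"leaf{i}", "center", weight=1.0)
            net.add_edge("center", f"leaf{i}", weight=1.0)
        for i in range(n_background):
            net.add_edge(f"b{i}", f"b{(i + 1) % n_background}", weight=1.0)
        return net

    def test_seeded_star_center_significant(self):
        net = self._star_net()
        res = seed_significance(net, {f"leaf{i}": 1.0 for i in range(10)},
                                n_rand=1000, alpha=0.1, seed=0)
        assert bool(res.significant["center"])

    def test_null_false_positive_rate_bounded(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(60, 0.1, directed=True, seed=5)
        net = nx.DiGraph()
        net.add_nodes_from(g.nodes())
        for a, b in g.edges():
            net.add_edge(a, b, weight=float(rng.uniform(0, 1)))
        rates = []
        for rep in range(10):
            seeds = {int(v): 1.0
                     for v in rng.choice(60, size=5, replace=False)}
            res = seed_significance(net, seeds, n_rand=1000, alpha=0.1,
                                    seed=rep)
            rates.append(res.significant.sum() / 55)
        assert np.mean(rates) <= 0.1 + 0.03

    def test_minimum_p_is_counting_floor(self):
        net = self._star_net(5, 50)
        res = seed_significance(net, {f"leaf{i}": 1.0 for i in range(5)},
                                n_rand=200, seed=1)
        assert res.p_value.min() >= 1 / 201

    def test_small_n_rand_rejected(self):
        net = self._star_net(3, 10)
        with pytest.raises(ValueError):
            seed_significance(net, {"leaf0": 1.0}, n_rand=50)

    def test_per_seed_decomposition_columns(self):
        net = self._star_net(4, 20)
        dec = per_seed_decomposition(net, {"leaf0": 1.0, "leaf1": 2.0})
        assert list(dec.columns) == ["leaf0", "leaf1"]
        assert np.allclose(dec.sum(axis=0), 1.0)


class TestShortestPaths:
    def test_single_chain_recovered(self):
        net = nx.DiGraph()
        net.add_edge("src", "a", weight=0.9)
        net.add_edge("a", "tgt", weight=0.9)
        sub, unreachable = shortest_path_subgraph(net, {"src"}, "tgt")
        assert sorted(sub.edges()) == [("a", "tgt"), ("src", "a")]
        assert unreachable == []

    def test_tied_paths_both_included(self):
        net = nx.DiGraph()
        for mid in ("x", "y"):
            net.add_edge("src", mid, weight=0.5)
            net.add_edge(mid, "tgt", weight=0.5)
        sub, _ = shortest_path_subgraph(net, {"src"}, "tgt")
        assert {"x", "y"} <= set(sub.nodes())

    def test_unreachable_source_reported(self):
        net = nx.DiGraph()
        net.add_edge("src", "tgt", weight=1.0)
        net.add_node("lonely")
        sub, unreachable = shortest_path_subgraph(net, {"src", "lonely"},
                                                  "tgt")
        assert unreachable == ["lonely"]

    def test_path_lengths_match_dijkstra_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.25, directed=True,
                                    seed=int(rng.integers(1e6)))
            net = nx.DiGraph()
            net.add_nodes_from(g.nodes())
            for a, b in g.edges():
                net.add_edge(a, b, weight=float(rng.uniform(0, 1)))
            dist = {(a, b): max(1 - abs(d["weight"]), 1e-6)
                    for a, b, d in net.edges(data=True)}
            nx.set_edge_attributes(net, dist, "check")
            target = 0
            sources = {int(v) for v in rng.choice(range(1, 15), size=3,
                                                  replace=False)}
            sub, unreachable = shortest_path_subgraph(net, sources, target)
            for s in sources - set(unreachable):
                expected = nx.shortest_path_length(net, s, target,
                                                   weight="check")
                got = nx.shortest_path_length(sub, s, target, weight="check")
                assert got == pytest.approx(expected, abs=1e-12)
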