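"""Phenotype-specific network assembly via prize-collecting Steiner forest.

Prize nodes (TFs regulating shape-correlated modules, differentially active
TFs, and enriched-pathway proteins) each carry a prize; edges of the signed
prior network carry costs derived from their citation counts.  The PCSF
solver connects the profitable prizes into a forest that minimizes

    sum(edge costs) + w * (number of trees) + sum(prizes left out),

with a hub penalty mu reducing the prize of high-degree nodes.  The solver
runs a virtual-root heuristic (metric-closure MST over terminals followed
by strong pruning); when the prior graph is a forest an exact dynamic
program is used instead, so tree instances are solved optimally.  The
solution is re-run under multiplicative cost noise and unioned across
iterations, then augmented with module supernodes, phenotype nodes and
feedback edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import Regulons, fisher_overlap

log = logging.getLogger(__name__)

_ROOT = "__pcsf_root__"


@dataclass
class PCSFParams:
    prize_value: float = 100.0
    b: float = 1.0
    w: float = 40.0
    mu: float = 0.005
    noise_frac: float = 0.05
    iterations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prize_value", "b", "w", "mu", "noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def validate_prior(prior: pd.DataFrame) -> pd.DataFrame:
    required = {"source", "target", "sign", "n_sources"}
    missing = required - set(prior.columns)
    if missing:
        raise ValueError(f"prior network missing columns {sorted(missing)}")
    if (prior["source"] == prior["target"]).any():
        raise ValueError("prior network contains self-loops")
    if (prior["n_sources"] < 1).any():
        raise ValueError("n_sources must be >= 1")
    if not prior["sign"].isin([1, -1]).all():
        raise ValueError("sign must be +1 or -1")
    return prior


def edge_costs(prior: pd.DataFrame) -> pd.Series:
    """Cost per edge: min-max scaled inverse citation count.

    ``s_e = 1 / n_sources``; costs are ``(s_e - min s) / (max s - min s)``
    (0.5 everywhere when all counts are equal), so the best-documented edge
    costs 0 and single-source edges cost 1.
    """
    validate_prior(prior)
    s = 1.0 / prior["n_sources"].to_numpy(dtype=float)
    if s.max() > s.min():
        cost = (s - s.min()) / (s.max() - s.min())
    else:
        cost = np.full_like(s, 0.5)
    return pd.Series(cost, index=prior.index, name="cost")


def prior_digraph(prior: pd.DataFrame) -> nx.DiGraph:
    """Directed prior graph with sign, n_sources and cost edge attributes."""
    costs = edge_costs(prior)
    g = nx.DiGraph()
    for (_, row), c in zip(prior.iterrows(), costs):
        g.add_edge(row["source"], row["target"], sign=int(row["sign"]),
                   n_sources=int(row["n_sources"]), cost=float(c))
    return g


def undirected_view(g: nx.DiGraph) -> nx.Graph:
    """Undirected solving view; parallel edges keep the cheaper cost."""
    u = nx.Graph()
    for a, b, d in g.edges(data=True):
        if u.has_edge(a, b):
            if d["cost"] < u[a][b]["cost"]:
                u[a][b].update(cost=d["cost"])
        else:
            u.add_edge(a, b, cost=d["cost"])
    return u


def collect_prizes(
    tf_module_hits: set[str],
    de_tf_hits: set[str],
    pathway_proteins: set[str],
    params: PCSFParams,
    prior_graph: nx.Graph | nx.DiGraph,
) -> dict[str, float]:
    """Effective prizes: ``max(b * prize - mu * degree, 0)`` per prize node.

    Degree is taken on the full prior network; prize nodes absent from the
    prior are kept (with a warning) at degree 0.
    """
    nodes = tf_module_hits | de_tf_hits | pathway_proteins
    und = prior_graph.to_undirected() if prior_graph.is_directed() else prior_graph
    prizes = {}
    for v in sorted(nodes):
        deg = und.degree(v) if v in und else 0
        if v not in und:
            log.warning("prize node %s absent from prior network", v)
        prizes[v] = max(params.b * params.prize_value - params.mu * deg, 0.0)
    return prizes


def pcsf_objective(
    solution: nx.Graph, prizes: dict[str, float], w: float
) -> float:
    """Objective value of a candidate forest (lower is better)."""
    cost = sum(d["cost"] for _, _, d in solution.edges(data=True))
    n_trees = nx.number_connected_components(solution) if len(solution) else 0
    missed = sum(p for v, p in prizes.items() if v not in solution)
    return cost + w * n_trees + missed


def _strong_prune(tree: nx.Graph, prizes: dict[str, float], w: float) -> nx.Graph:
    """Strong pruning of a tree containing the virtual root.

    Bottom-up net worth ``nw(v) = prize(v) + sum_c max(0, nw(c) - cost)``;
    a child subtree survives only if its net worth exceeds the cost of the
    edge to it (the root's children must beat w).
    """
    order = list(nx.dfs_postorder_nodes(tree, _ROOT))
    parent = dict(nx.dfs_predecessors(tree, _ROOT))
    nw: dict[str, float] = {}
    keep_edge: dict[str, bool] = {}
    children: dict[str, list[str]] = {v: [] for v in tree}
    for v, p in parent.items():
        children[p].append(v)
    for v in order:
        if v == _ROOT:
            continue
        val = prizes.get(v, 0.0)
        for c in children[v]:
            gain = nw[c] - tree[v][c]["cost"]
            keep_edge[c] = gain > 0
            if gain > 0:
                val += gain
        nw[v] = val
    for c in children[_ROOT]:
        keep_edge[c] = nw[c] - w > 0

    out = nx.Graph()
    frontier = [c for c in children[_ROOT] if keep_edge[c]]
    for start in frontier:
        out.add_node(start)
        stack = [start]
        while stack:
            v = stack.pop()
            for c in children[v]:
                if keep_edge.get(c):
                    out.add_edge(v, c, cost=tree[v][c]["cost"])
                    stack.append(c)
    return out


def _forest_dp(
    graph: nx.Graph, prizes: dict[str, float], w: float
) -> nx.Graph:
    """Exact PCSF on forest-shaped priors by dynamic programming."""
    sol = nx.Graph()
    for comp in nx.connected_components(graph):
        tree = graph.subgraph(comp)
        root = min(comp)
        parent = dict(nx.dfs_predecessors(tree, root))
        children: dict[str, list[str]] = {v: [] for v in tree}
        for v, p in parent.items():
            children[p].append(v)
        order = list(nx.dfs_postorder_nodes(tree, root))
        open_v: dict[str, float] = {}
        best_v: dict[str, float] = {}
        join: dict[str, bool] = {}  # child joins parent's open tree
        for v in order:
            o = prizes.get(v, 0.0)
            b = 0.0
            for c in children[v]:
                joined = open_v[c] - tree[v][c]["cost"]
                if joined > best_v[c]:
                    o += joined
                    join[c] = True
                else:
                    o += best_v[c]
                    join[c] = False
                b += best_v[c]
            open_v[v] = o
            best_v[v] = max(o - w, b)

        # traceback: state per node, "open" = belongs to the tree opened at
        # its highest open ancestor, "free" = take best (closed forest)
        def emit_open(v: str) -> None:
            sol.add_node(v)
            for c in children[v]:
                if join[c]:
                    sol.add_edge(v, c, cost=tree[v][c]["cost"])
                    emit_open(c)
                else:
                    emit_free(c)

        def emit_free(v: str) -> None:
            if open_v[v] - w > sum(best_v[c] for c in children[v]):
                emit_open(v)
            else:
                for c in children[v]:
                    emit_free(c)

        emit_free(root)
    return sol


def _heuristic(
    graph: nx.Graph, prizes: dict[str, float], w: float
) -> nx.Graph:
    terminals = [v for v, p in prizes.items() if p > 0 and v in graph]
    best: nx.Graph | None = None
    best_obj = float("inf")

    def consider(candidate_edges: nx.Graph) -> None:
        nonlocal best, best_obj
        aug = nx.Graph()
        for a, b, d in candidate_edges.edges(data=True):
            aug.add_edge(a, b, cost=d["cost"])
        for t in terminals:
            aug.add_edge(_ROOT, t, cost=w)
        if _ROOT not in aug:
            return
        mst = nx.minimum_spanning_tree(aug, weight="cost")
        pruned = _strong_prune(mst, prizes, w)
        obj = pcsf_objective(pruned, prizes, w)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best = pruned

    if terminals:
        # candidate 1: expansion of the metric-closure MST over terminals
        closure = nx.Graph()
        paths: dict[str, dict[str, list[str]]] = {}
        for t in terminals:
            dist, path = nx.single_source_dijkstra(graph, t, weight="cost")
            paths[t] = path
            for u in terminals:
                if u != t and u in dist:
                    closure.add_edge(t, u, cost=dist[u])
            closure.add_edge(_ROOT, t, cost=w)
        cmst = nx.minimum_spanning_tree(closure, weight="cost")
        expanded = nx.Graph()
        for a, b in cmst.edges():
            if _ROOT in (a, b):
                continue
            path = paths[a][b]
            for u, v in zip(path, path[1:]):
                expanded.add_edge(u, v, cost=graph[u][v]["cost"])
        consider(expanded)
        # candidate 2: MST over the full graph
        consider(graph)

    empty = nx.Graph()
    if pcsf_objective(empty, prizes, w) < best_obj:
        best = empty
    return best if best is not None else nx.Graph()


def pcsf_solve(
    graph: nx.Graph, prizes: dict[str, float], params: PCSFParams
) -> nx.Graph:
    """One PCSF run on the undirected solving view.

    Returns the selected forest as an undirected graph with edge costs.
    Prize nodes absent from ``graph`` are kept as isolated trees when their
    prize exceeds the per-tree charge w.
    """
    active = {v: p for v, p in prizes.items() if p > 0}
    if not active:
        return nx.Graph()
    if len(graph) and nx.is_forest(graph):
        sol = _forest_dp(graph, active, params.w)
    else:
        sol = _heuristic(graph, active, params.w)
    for v, p in active.items():
        if v not in graph and p > params.w:
            sol.add_node(v)
    return sol


def pcsf_union(
    graph: nx.Graph,
    prizes: dict[str, float],
    params: PCSFParams,
) -> nx.Graph:
    """Union of PCSF solutions under multiplicative edge-cost noise.

    Each of ``params.iterations`` runs perturbs every cost by
    ``(1 + u), u ~ Uniform(-noise_frac, +noise_frac)`` and re-solves;
    the union of the per-run forests is returned (costs from the unperturbed
    graph).  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    union = nx.Graph()
    edges = sorted(graph.edges())
    for _ in range(params.iterations):
        noisy = nx.Graph()
        for a, b in edges:
            u = rng.uniform(-params.noise_frac, params.noise_frac)
            noisy.add_edge(a, b, cost=graph[a][b]["cost"] * (1.0 + u))
        sol = pcsf_solve(noisy, prizes, params)
        union.add_nodes_from(sol.nodes())
        for a, b in sol.edges():
            union.add_edge(a, b, cost=graph[a][b]["cost"])
        if params.noise_frac == 0:
            break  # identical runs
    return union


def assemble_network(
    prior: pd.DataFrame, solution: nx.Graph
) -> nx.DiGraph:
    """Directed assembled network: solution edges with prior sign restored."""
    g = prior_digraph(prior)
    net = nx.DiGraph()
    for v in solution.nodes():
        net.add_node(v, kind="protein")
    for a, b in solution.edges():
        for u, v in ((a, b), (b, a)):
            if g.has_edge(u, v):
                d = g[u][v]
                net.add_edge(u, v, sign=d["sign"], weight=1.0,
                             cost=d["cost"], origin="pcsf")
        if not (g.has_edge(a, b) or g.has_edge(b, a)):
            net.add_edge(a, b, sign=1, weight=1.0, cost=0.0, origin="pcsf")
    return net


def add_supernodes(
    net: nx.DiGraph,
    modules: dict[str, list[str]],
    regulons: Regulons,
    shape_corr,
    universe: set[str],
    alpha_tf: float = 0.1,
    r_threshold: float = 0.5,
    alpha_corr: float = 0.05,
) -> nx.DiGraph:
    """Augment a PCSF network with module supernodes and phenotype nodes.

    Per module: incoming edges from in-network TFs whose regulon overlaps
    the module (Fisher p < alpha_tf, activatory and inhibitory directions
    tested separately with unknown-sign targets in both); undirected edges
    to phenotype nodes whose eigengene correlation satisfies
    ``|r| > r_threshold and p < alpha_corr``; and weight-1 feedback edges
    from the supernode to member proteins present in the network.
    ``shape_corr`` is a ModuleShapeCorrelation for the same modules.
    """
    out = net.copy()
    protein_nodes = {v for v, d in out.nodes(data=True)
                     if d.get("kind") == "protein"}
    for mod, genes in modules.items():
        sn = f"GEM:{mod}"
        out.add_node(sn, kind="gem_supernode")
        gene_set = set(genes)
        connected = False
        for tf, sets in regulons.items():
            if tf not in protein_nodes:
                continue
            unk = sets.get("unknown", set())
            for direction, targets in (
                (1, sets.get("activated", set()) | unk),
                (-1, sets.get("repressed", set()) | unk),
            ):
                if not targets:
                    continue
                p, _ = fisher_overlap(targets, gene_set, universe)
                if p < alpha_tf:
                    out.add_edge(tf, sn, sign=direction, weight=1.0,
                                 origin="tf-gem", p=p)
                    connected = True
                    break
        if not connected:
            log.info("module %s has no qualifying in-network TF", mod)
        if shape_corr is not None and mod in shape_corr.pcc.index:
            for feat in shape_corr.pcc.columns:
                r = shape_corr.pcc.loc[mod, feat]
                p = shape_corr.p_student.loc[mod, feat]
                if abs(r) > r_threshold and p < alpha_corr:
                    ph = f"PHENO:{feat}"
                    out.add_node(ph, kind="phenotype")
                    s = 1 if r > 0 else -1
                    out.add_edge(sn, ph, sign=s, weight=1.0,
                                 origin="gem-phenotype", r=float(r))
                    out.add_edge(ph, sn, sign=s, weight=1.0,
                                 origin="gem-phenotype", r=float(r))
        for g in sorted(gene_set & protein_nodes):
            out.add_edge(sn, g, sign=1, weight=1.0, origin="feedback")
        if out.degree(sn) == 0:
            log.info("dropping isolated supernode %s", sn)
            out.remove_node(sn)
    return out


def network_stats(
    net: nx.DiGraph, prizes: dict[str, float] | None = None
) -> dict:
    """Degree distribution, betweenness ranking and prize coverage."""
    if len(net) == 0:
        raise ValueError("empty network")
    und = net.to_undirected()
    for a, b, d in und.edges(data=True):
        d["distance"] = d.get("cost", 1.0 - abs(d.get("weight", 1.0)) + 1e-6)
    betw = nx.betweenness_centrality(und, weight="distance", normalized=False)
    ranking = sorted(betw.items(), key=lambda kv: -kv[1])
    degrees = dict(und.degree())
    coverage = float("nan")
    if prizes:
        in_net = sum(1 for v in prizes if v in net)
        coverage = in_net / len(prizes)
    return {
        "degree": degrees,
        "betweenness": ranking,
        "prize_coverage": coverage,
        "n_nodes": len(net),
        "n_edges": net.number_of_edges(),
    }
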