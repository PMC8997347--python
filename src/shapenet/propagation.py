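"""Semantic-similarity edge weights and random-walk-with-restart diffusion.

Protein-protein edge weights are replaced by the Resnik best-match-average
(BMA) semantic similarity of the two genes' ontology annotations, min-max
scaled to [0, 1] and then signed by the prior interaction sign, giving
weights in [-1, 1].  TF activity seeds are diffused with a random walk with
restart (restart probability r, default 0.95); per-node significance comes
from re-running the walk with the same seed masses placed on uniformly
random node sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class OntologyDAG:
    """Rooted term DAG with gene annotations and information content.

    ``parents`` maps each term to its parent set (the root has none);
    ``annotations`` maps genes to directly annotated terms.  A term's
    information content is ``-ln`` of the fraction of annotated genes that
    carry the term or any of its descendants (ancestor-propagated counts),
    so the root always has IC 0.
    """

    def __init__(
        self,
        parents: dict[str, set[str]],
        annotations: dict[str, set[str]],
    ) -> None:
        self.parents = {t: set(p) for t, p in parents.items()}
        roots = [t for t, p in self.parents.items() if not p]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root term, got {roots}")
        self.root = roots[0]
        self.annotations = {
            g: set(t) & set(self.parents) for g, t in annotations.items()
        }
        self._ancestors: dict[str, frozenset[str]] = {}
        self._ic: dict[str, float] | None = None

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of a term, including the term itself."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        res = frozenset(out)
        self._ancestors[term] = res
        return res

    def gene_terms(self, gene: str) -> set[str]:
        """All terms a gene is annotated to, closed under ancestors."""
        out: set[str] = set()
        for t in self.annotations.get(gene, ()):
            out |= self.ancestors(t)
        return out

    @property
    def ic(self) -> dict[str, float]:
        if self._ic is None:
            counts: dict[str, int] = {t: 0 for t in self.parents}
            n_genes = 0
            for gene in self.annotations:
                terms = self.gene_terms(gene)
                if not terms:
                    continue
                n_genes += 1
                for t in terms:
                    counts[t] += 1
            if n_genes == 0:
                raise ValueError("no annotated genes")
            self._ic = {
                t: (-np.log(c / n_genes) if c > 0 else float("inf"))
                for t, c in counts.items()
            }
            self._ic[self.root] = 0.0
        return self._ic


def resnik_pairwise(onto: OntologyDAG, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor of two terms."""
    common = onto.ancestors(t1) & onto.ancestors(t2)
    if not common:
        return 0.0
    ic = onto.ic
    return max(ic[t] for t in common if np.isfinite(ic[t]))


def resnik_bma(onto: OntologyDAG, gene_a: str, gene_b: str) -> float:
    """Resnik best-match-average similarity between two genes.

    Mean over A's terms of the best pairwise similarity to B's terms,
    averaged with the symmetric direction.  Unannotated genes give 0 with a
    warning.
    """
    ta = sorted(onto.annotations.get(gene_a, ()))
    tb = sorted(onto.annotations.get(gene_b, ()))
    if not ta or not tb:
        log.warning("gene %s unannotated; similarity 0",
                    gene_a if not ta else gene_b)
        return 0.0
    sims = np.array([[resnik_pairwise(onto, a, b) for b in tb] for a in ta])
    return float(0.5 * (sims.max(axis=1).mean() + sims.max(axis=0).mean()))


def reweight_edges(net: nx.DiGraph, onto: OntologyDAG) -> nx.DiGraph:
    """Replace protein-protein edge weights by signed scaled similarity.

    Similarity is min-max scaled to [0, 1] over the protein-protein edges
    and multiplied by the prior sign, so weights land in [-1, 1].  Supernode
    and phenotype edges keep weight (and unsigned similarity) 1.  The raw
    scaled similarity is stored as the ``similarity`` edge attribute for use
    as a flow capacity.
    """
    out = net.copy()
    kind = nx.get_node_attributes(out, "kind")
    pp_edges = [
        (a, b) for a, b in out.edges()
        if kind.get(a, "protein") == "protein"
        and kind.get(b, "protein") == "protein"
    ]
    cache: dict[frozenset, float] = {}
    sims = []
    for a, b in pp_edges:
        key = frozenset((a, b))
        if key not in cache:
            cache[key] = resnik_bma(onto, a, b)
        sims.append(cache[key])
    sims = np.asarray(sims, dtype=float)
    if len(sims):
        lo, hi = sims.min(), sims.max()
        scaled = (sims - lo) / (hi - lo) if hi > lo else np.full_like(sims, 0.5)
    else:
        scaled = sims
    pp_set = set(pp_edges)
    for (a, b), s in zip(pp_edges, scaled):
        out[a][b]["similarity"] = float(s)
        out[a][b]["weight"] = float(s * out[a][b].get("sign", 1))
    for a, b, d in out.edges(data=True):
        if (a, b) not in pp_set:
            d["similarity"] = 1.0
    return out


@dataclass
class RWRResult:
    probability: pd.Series
    restart: float
    seeds: dict[str, float]
    p_value: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    significant: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))


def _transition_matrix(
    net: nx.DiGraph, nodes: list[str], mode: str = "positive"
) -> np.ndarray:
    """Row-normalized transition matrix from edge weights.

    ``mode='positive'`` keeps max(weight, 0) (negative regulation carries no
    walk probability); ``mode='absolute'`` uses |weight|.  Rows of dangling
    nodes are left all-zero; the walk returns their mass to the seeds.
    """
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for a, b, d in net.edges(data=True):
        w = d.get("weight", 1.0)
        w = abs(w) if mode == "absolute" else max(w, 0.0)
        W[idx[a], idx[b]] = w
    rowsum = W.sum(axis=1)
    nz = rowsum > 0
    W[nz] /= rowsum[nz, None]
    return W


def _solve_rwr(
    W: np.ndarray, S: np.ndarray, r: float, tol: float = 1e-10
) -> np.ndarray:
    """Iterate ``p = r s + (1-r)(W^T p + s * dangling_mass)`` per column.

    ``S`` holds one seed distribution per column (each summing to 1); the
    fixed point is proportional to the closed form
    ``(I - (1-r) W^T)^{-1} s`` renormalized to total mass 1.
    """
    dangling = W.sum(axis=1) == 0
    P = S.copy()
    WT = W.T
    for _ in range(10000):
        dang_mass = P[dangling].sum(axis=0)
        nxt = r * S + (1 - r) * (WT @ P + S * dang_mass)
        delta = np.abs(nxt - P).sum(axis=0).max()
        P = nxt
        if delta < tol:
            break
    return P


def rwr(
    net: nx.DiGraph,
    seeds: dict[str, float],
    restart: float = 0.95,
    mode: str = "positive",
) -> RWRResult:
    """Random walk with restart from weighted seed nodes.

    Seed masses must be non-negative with positive sum; they are normalized
    to a probability vector.  Returns stationary visitation probabilities
    summing to 1.
    """
    if not 0 < restart < 1:
        raise ValueError("restart must lie in (0, 1)")
    total = sum(seeds.values())
    if total <= 0 or any(v < 0 for v in seeds.values()):
        raise ValueError("seed masses must be >= 0 with positive sum")
    nodes = sorted(net.nodes())
    missing = [v for v in seeds if v not in net]
    if missing:
        raise ValueError(f"seed nodes absent from network: {missing}")
    s = np.zeros(len(nodes))
    for v, m in seeds.items():
        s[nodes.index(v)] = m / total
    W = _transition_matrix(net, nodes, mode)
    if not W.any():
        log.warning("no positive-weight edges; returning seed distribution")
        return RWRResult(pd.Series(s, index=nodes), restart, dict(seeds))
    P = _solve_rwr(W, s[:, None], restart)
    return RWRResult(pd.Series(P[:, 0], index=nodes), restart, dict(seeds))


def seed_significance(
    net: nx.DiGraph,
    seeds: dict[str, float],
    n_rand: int = 10000,
    alpha: float = 0.1,
    restart: float = 0.95,
    seed: int = 0,
    mode: str = "positive",
) -> RWRResult:
    """Empirical significance of RWR affinities under seed randomization.

    The observed seed masses are reassigned ``n_rand`` times to uniformly
    sampled node sets of the same size (values preserved); for each
    non-seed node ``p = (1 + #{random affinity >= observed}) / (n_rand + 1)``
    and the node is flagged significant when ``p < alpha``.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100")
    nodes = sorted(net.nodes())
    if len(seeds) >= len(nodes):
        raise ValueError("seeds must be a strict subset of nodes")
    obs = rwr(net, seeds, restart, mode)

    rng = np.random.default_rng(seed)
    masses = np.array([m for _, m in sorted(seeds.items())], dtype=float)
    masses = masses / masses.sum()
    n = len(nodes)
    S = np.zeros((n, n_rand))
    for b in range(n_rand):
        loc = rng.choice(n, size=len(masses), replace=False)
        S[loc, b] = masses
    W = _transition_matrix(net, nodes, mode)
    P = _solve_rwr(W, S, restart)

    obs_v = obs.probability.to_numpy()
    exceed = (P >= obs_v[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_rand + 1.0)
    p_ser = pd.Series(p, index=nodes)
    seed_nodes = set(seeds)
    p_ser[p_ser.index.isin(seed_nodes)] = np.nan
    sig = (p_ser < alpha).fillna(False)
    return RWRResult(obs.probability, restart, dict(seeds), p_ser, sig)


def per_seed_decomposition(
    net: nx.DiGraph,
    seeds: dict[str, float],
    restart: float = 0.95,
    mode: str = "positive",
) -> pd.DataFrame:
    """RWR run for each seed alone; columns are seeds, rows are nodes."""
    cols = {}
    for v, m in sorted(seeds.items()):
        cols[v] = rwr(net, {v: m}, restart, mode).probability
    return pd.DataFrame(cols)


def shortest_path_subgraph(
    net: nx.DiGraph,
    sources: set[str],
    target: str,
    eps: float = 1e-6,
) -> tuple[nx.DiGraph, list[str]]:
    """Union of all shortest paths from each source to the target.

    Edge distance is ``1 - |weight|`` floored at ``eps``.  Returns the
    subgraph and the list of sources that cannot reach the target.
    """
    if target not in net:
        raise ValueError(f"target {target} absent from network")
    dist = {
        (a, b): max(1.0 - abs(d.get("weight", 1.0)), eps)
        for a, b, d in net.edges(data=True)
    }
    g = net.copy()
    nx.set_edge_attributes(g, dist, "distance")
    sub = nx.DiGraph()
    unreachable = []
    for src in sorted(sources):
        if src not in g:
            unreachable.append(src)
            continue
        try:
            for path in nx.all_shortest_paths(g, src, target, weight="distance"):
                for u, v in zip(path, path[1:]):
                    sub.add_edge(u, v, **g[u][v])
        except nx.NetworkXNoPath:
            unreachable.append(src)
    if not sub:
        log.warning("no source reaches target %s", target)
    return sub, unreachable
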