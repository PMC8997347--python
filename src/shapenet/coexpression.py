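"""Signed weighted coexpression networks and shape-correlated modules.

The adjacency between genes i and j is ``a_ij = |(1 + cor(x_i, x_j)) / 2|^beta``
computed on log2-transformed expression, so strongly anti-correlated genes
get adjacency near 0 (signed-network reading).  Adjacency is converted to
the unsigned topological overlap measure (TOM); modules come from
average-linkage clustering of 1 - TOM with a static cut, a minimum size
rule and iterative eigengene merging.  Module eigengenes are correlated with
shape features with Student asymptotic p-values plus a rank-based
permutation multiple-testing procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class CoexpressionParams:
    beta: int = 9
    min_module_size: int = 30
    # fraction of the max merge height for the static cut; background genes
    # merge only near the top of the tree, so 0.9 separates them cleanly
    cut_height: float = 0.9
    merge_corr: float = 0.85

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")
        if not 0 < self.merge_corr < 1:
            raise ValueError("merge_corr must lie in (0, 1)")


@dataclass
class ModuleSet:
    """Detected coexpression modules with their eigengenes."""

    modules: dict[str, list[str]]
    eigengenes: pd.DataFrame  # samples x module labels, unit variance
    unassigned: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.modules)

    def sizes(self) -> dict[str, int]:
        return {m: len(g) for m, g in self.modules.items()}


@dataclass
class ModuleShapeCorrelation:
    pcc: pd.DataFrame
    p_student: pd.DataFrame
    p_perm: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    significant: pd.DataFrame


def filter_genes(
    expr: pd.DataFrame, coding: set[str] | None, fpkm_min: float = 1.0
) -> pd.DataFrame:
    """Keep protein-coding genes expressed above ``fpkm_min`` in >=1 sample."""
    keep = expr.max(axis=1) > fpkm_min
    if coding is not None:
        keep &= expr.index.isin(coding)
    out = expr.loc[keep]
    if out.empty:
        log.warning("gene filter removed every gene")
    return out


def adjacency(expr_log2: pd.DataFrame, beta: int = 9) -> pd.DataFrame:
    """Soft-thresholded signed adjacency |(1 + cor)/2|^beta.

    ``expr_log2`` is genes x samples, already log2-scale.  Genes with zero
    variance get correlation 0 with everything (adjacency (1/2)^beta).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr_log2.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr_log2.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.info("%d constant genes assigned correlation 0", constant.sum())
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(x.shape[1]))
    xn = xc / denom[:, None]
    cor = xn @ xn.T
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    np.clip(cor, -1.0, 1.0, out=cor)
    a = np.abs((1.0 + cor) / 2.0) ** beta
    return pd.DataFrame(a, index=expr_log2.index, columns=expr_log2.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned TOM similarity.

    ``t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with the
    sum over u != i, j and ``k_i = sum_{u != i} a_iu``; diagonal set to 1.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # a_ii = 0 so u = i, j terms vanish
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def eigengene(expr_log2: pd.DataFrame, genes: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Unit variance across samples, sign-oriented to correlate positively
    with the module's mean standardized profile.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = expr_log2.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    if not np.any(z):
        raise ValueError("rank-0 module submatrix")
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    pc = pc / pc.std()
    return pd.Series(pc, index=expr_log2.columns)


def _jaccard(a: set, b: set) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def best_match_jaccard(
    detected: dict[str, list[str]], truth: dict[str, list[str]]
) -> dict[str, float]:
    """For each truth module, the best Jaccard against detected modules."""
    out = {}
    for label, genes in truth.items():
        gs = set(genes)
        out[label] = max(
            (_jaccard(gs, set(d)) for d in detected.values()), default=0.0
        )
    return out


def detect_modules(
    dissimilarity: pd.DataFrame,
    expr_log2: pd.DataFrame,
    params: CoexpressionParams | None = None,
) -> ModuleSet:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    Static cut at ``cut_height`` x max merge height; clusters below
    ``min_module_size`` go to unassigned; modules whose eigengenes correlate
    above ``merge_corr`` are merged iteratively to a fixed point.
    """
    params = params or CoexpressionParams()
    genes = list(dissimilarity.index)
    d = dissimilarity.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    height = params.cut_height * link[:, 2].max() if len(link) else 0.0
    labels = fcluster(link, t=height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(g)

    modules = {}
    unassigned: list[str] = []
    for lab in sorted(clusters):
        members = clusters[lab]
        if len(members) >= params.min_module_size:
            modules[f"M{len(modules) + 1}"] = members
        else:
            unassigned.extend(members)

    if not modules:
        log.warning("module detection produced no modules above minimum size")
        return ModuleSet({}, pd.DataFrame(index=expr_log2.columns), unassigned)

    # iterative eigengene merge
    changed = True
    while changed and len(modules) > 1:
        changed = False
        egs = {m: eigengene(expr_log2, g) for m, g in modules.items()}
        labels_ = list(modules)
        for i in range(len(labels_)):
            for j in range(i + 1, len(labels_)):
                a, b = labels_[i], labels_[j]
                r = float(np.corrcoef(egs[a], egs[b])[0, 1])
                if r > params.merge_corr:
                    modules[a] = modules[a] + modules[b]
                    del modules[b]
                    changed = True
                    break
            if changed:
                break

    modules = {f"M{i + 1}": g for i, g in enumerate(modules.values())}
    egs = pd.DataFrame(
        {m: eigengene(expr_log2, g) for m, g in modules.items()}
    )
    return ModuleSet(modules, egs, unassigned)


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlations: (x cols) x (y cols)."""
    xn = (x - x.mean(0)) / x.std(0)
    ys = y.std(0)
    ys[ys == 0] = 1.0
    yn = (y - y.mean(0)) / ys
    return (xn.T @ yn) / x.shape[0]


def correlate_modules_shape(
    eigengenes: pd.DataFrame,
    shape: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
) -> ModuleShapeCorrelation:
    """Module-eigengene vs shape-feature correlation with permutation null.

    Pearson r per (module, feature) with Student asymptotic p.  The
    multiple-testing procedure permutes sample labels of the shape table
    ``n_perm`` times, recomputes the full |r| matrix each time, sorts its
    entries, and compares the observed statistic of each rank against the
    null distribution of that rank: ``p_perm = (1 + #{null_k >= obs_k}) /
    (n_perm + 1)``, with a binomial (Wilson) CI on each p.  The significance
    flag follows ``|r| > r_threshold and p_student < alpha``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    common = eigengenes.index.intersection(shape.index)
    n = len(common)
    if n < 4:
        raise ValueError("need at least 4 aligned samples")
    eg = eigengenes.loc[common].to_numpy(dtype=float)
    sh = shape.loc[common].to_numpy(dtype=float)

    r = _pearson_matrix(eg, sh)
    nm, nf = r.shape
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p_student = 2 * stats.t.sf(np.abs(t), df=n - 2)

    # rank-based permutation null on |r|
    flat = np.abs(r).ravel()
    order = np.argsort(flat)[::-1]  # descending rank
    obs_sorted = flat[order]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(flat.size)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null_r = np.abs(_pearson_matrix(eg, sh[perm]))
        null_sorted = np.sort(null_r.ravel())[::-1]
        exceed += null_sorted >= obs_sorted
    p_perm_sorted = (1.0 + exceed) / (n_perm + 1.0)
    p_perm = np.empty_like(flat)
    p_perm[order] = p_perm_sorted

    # Wilson binomial CI on the exceedance proportion
    k = np.empty_like(flat)
    k[order] = exceed
    lo, hi = _wilson_interval(k, n_perm)

    idx, cols = eigengenes.columns, shape.columns
    as_df = lambda m: pd.DataFrame(m.reshape(nm, nf), index=idx, columns=cols)
    significant = (np.abs(r) > r_threshold) & (p_student < alpha)
    return ModuleShapeCorrelation(
        pcc=as_df(r.ravel()),
        p_student=as_df(p_student.ravel()),
        p_perm=as_df(p_perm),
        ci_low=as_df(lo),
        ci_high=as_df(hi),
        significant=as_df(significant.ravel()).astype(bool),
    )


def _wilson_interval(k: np.ndarray, n: int, z: float = 1.96):
    p = (k + 1) / (n + 1)
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def jackknife_modules(
    expr_log2: pd.DataFrame,
    params: CoexpressionParams | None = None,
    reference: ModuleSet | None = None,
) -> pd.DataFrame:
    """Leave-one-sample-out stability of module detection.

    Re-detects modules on each fold and reports, per reference module, the
    mean and min best-match Jaccard across folds.
    """
    params = params or CoexpressionParams()
    if expr_log2.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if reference is None:
        adj = adjacency(expr_log2, params.beta)
        tom = topological_overlap(adj)
        reference = detect_modules(1 - tom, expr_log2, params)

    per_fold: dict[str, list[float]] = {m: [] for m in reference.modules}
    for s in expr_log2.columns:
        sub = expr_log2.drop(columns=[s])
        adj = adjacency(sub, params.beta)
        tom = topological_overlap(adj)
        det = detect_modules(1 - tom, sub, params)
        bm = best_match_jaccard(det.modules, reference.modules)
        for m in per_fold:
            per_fold[m].append(bm.get(m, 0.0))
    rows = [
        (m, float(np.mean(v)), float(np.min(v))) for m, v in per_fold.items()
    ]
    return pd.DataFrame(rows, columns=["module", "mean_jaccard", "min_jaccard"])
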