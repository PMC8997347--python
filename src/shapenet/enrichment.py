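"""Exact-test enrichment: regulon/module overlap, TF->pathway scoring,
module-resampling nulls and preranked gene-set enrichment.

All over-representation tests are one-sided Fisher exact tests evaluated as
hypergeometric tail sums; FDR control is Benjamini-Hochberg throughout.
The combined pathway score follows the -ln(p) x z construction, where z is
the deviation of a pathway's observed rank from its expected rank over
random query sets of matched size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

Regulons = dict[str, dict[str, set[str]]]
GeneSets = dict[str, set[str]]


def fisher_overlap(
    query: set[str], reference: set[str], universe: set[str]
) -> tuple[float, float]:
    """One-sided Fisher exact test for over-representation.

    Returns ``(p, odds_ratio)`` from the 2x2 table of query x reference
    within universe; the odds ratio uses the Haldane 0.5 correction whenever
    a cell is empty.
    """
    if not universe:
        raise ValueError("empty universe")
    q = query & universe
    ref = reference & universe
    k = len(q & ref)
    K = len(ref)
    n = len(q)
    M = len(universe)
    if n == 0 or K == 0:
        return 1.0, 0.0
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    a, b, c, d = k, n - k, K - k, M - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return p, (a * d) / (b * c)


@dataclass
class EnrichmentResult:
    term: str
    p: float
    odds_ratio: float
    combined_score: float
    fdr: float
    overlap_genes: set[str]


def regulon_module_enrichment(
    modules: dict[str, list[str]],
    regulons: Regulons,
    universe: set[str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per (TF, module) regulon-overlap tests, split by direction.

    Activatory and inhibitory target sets are each tested after union with
    the unknown-sign targets.  Columns: tf, module, direction, p,
    odds_ratio, overlap, significant (p < alpha).
    """
    rows = []
    for tf, sets in regulons.items():
        act = sets.get("activated", set())
        rep = sets.get("repressed", set())
        unk = sets.get("unknown", set())
        if not (act | rep | unk):
            log.info("TF %s has no targets; skipped", tf)
            continue
        for direction, targets in (
            ("activatory", act | unk),
            ("inhibitory", rep | unk),
        ):
            if not targets:
                continue
            for mod, genes in modules.items():
                p, orr = fisher_overlap(targets, set(genes), universe)
                overlap = len(targets & set(genes) & universe)
                rows.append((tf, mod, direction, p, orr, overlap, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["tf", "module", "direction", "p", "odds_ratio", "overlap",
                 "significant"],
    )


def significant_tfs(table: pd.DataFrame) -> set[str]:
    """TFs significant for any module/direction in a regulon-module table."""
    if table.empty:
        return set()
    return set(table.loc[table["significant"], "tf"])


def tf_pathway_enrichment(
    tfs: set[str],
    genesets: GeneSets,
    universe: set[str],
    n_rank_perm: int = 200,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Pathway enrichment of a TF set with a rank-deviation combined score.

    Each pathway gets a one-sided Fisher p; pathways are then ranked by p,
    and the z-score of each pathway's observed rank against the distribution
    of its rank over ``n_rank_perm`` random query sets of the same size
    feeds ``combined_score = -ln(p) * z`` (z floored at 0).  FDR is BH
    across pathways.
    """
    terms = sorted(genesets)
    ps, odds, overlaps = [], [], []
    for term in terms:
        p, orr = fisher_overlap(tfs, genesets[term], universe)
        ps.append(p)
        odds.append(orr)
        overlaps.append(tfs & genesets[term] & universe)
    ps_arr = np.array(ps)
    obs_rank = stats.rankdata(ps_arr, method="average")

    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    q = min(len(tfs & universe), len(uni))
    null_ranks = np.zeros((n_rank_perm, len(terms)))
    for b in range(n_rank_perm):
        rand_q = set(rng.choice(uni, size=q, replace=False)) if q else set()
        null_p = np.array(
            [fisher_overlap(rand_q, genesets[t], universe)[0] for t in terms]
        )
        null_ranks[b] = stats.rankdata(null_p, method="average")
    mu = null_ranks.mean(axis=0)
    sd = null_ranks.std(axis=0)
    sd[sd == 0] = 1.0
    z = np.maximum((mu - obs_rank) / sd, 0.0)  # better-than-expected rank

    fdr = multipletests(ps_arr, method="fdr_bh")[1]
    results = []
    for i, term in enumerate(terms):
        combined = float(-np.log(max(ps_arr[i], 1e-300)) * z[i])
        if ps_arr[i] >= 1.0:
            combined = 0.0
        results.append(
            EnrichmentResult(term, float(ps_arr[i]), float(odds[i]), combined,
                             float(fdr[i]), overlaps[i])
        )
    return sorted(results, key=lambda r: r.p)


def _pathway_p_chain(
    module_genes: set[str],
    regulons: Regulons,
    genesets: GeneSets,
    gene_universe: set[str],
    tf_universe: set[str],
    alpha_tf: float = 0.1,
) -> dict[str, float]:
    """Module -> TF enrichment -> pathway Fisher p, the chain run per module.

    Pathways with no enriched TF get p = 1 (a failed test).
    """
    hits = set()
    for tf, sets in regulons.items():
        act = sets.get("activated", set()) | sets.get("unknown", set())
        rep = sets.get("repressed", set()) | sets.get("unknown", set())
        for targets in (act, rep):
            if targets and fisher_overlap(targets, module_genes,
                                          gene_universe)[0] < alpha_tf:
                hits.add(tf)
                break
    if not hits:
        return {t: 1.0 for t in genesets}
    return {
        t: fisher_overlap(hits, genesets[t], tf_universe)[0] for t in genesets
    }


def resampled_pathway_null(
    module_sizes: list[int],
    observed_p: dict[str, float],
    regulons: Regulons,
    genesets: GeneSets,
    gene_universe: set[str],
    tf_universe: set[str],
    n_resample: int = 1000,
    alpha_tf: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Pathway-bias null from size-matched random modules.

    Draws ``n_resample`` random gene modules matching the observed module
    size profile, runs the full TF-enrichment -> pathway-enrichment chain on
    each, and compares each observed pathway p to its null distribution:
    ``empirical_p = (1 + #{null <= observed}) / (n_resample + 1)``, BH
    adjusted across pathways.  Failed chains (no TF enrichment) contribute
    p = 1 to the null.
    """
    if n_resample < 50:
        raise ValueError("need at least 50 resamples for a stable null")
    rng = np.random.default_rng(seed)
    uni = sorted(gene_universe)
    null_ps = {t: np.empty(n_resample) for t in genesets}
    for b in range(n_resample):
        # one random module per observed size; chain p = min over modules,
        # mirroring "any module enriches the pathway"
        chain = {t: 1.0 for t in genesets}
        for size in module_sizes:
            mod = set(rng.choice(uni, size=min(size, len(uni)), replace=False))
            ps = _pathway_p_chain(mod, regulons, genesets, gene_universe,
                                  tf_universe, alpha_tf)
            for t, p in ps.items():
                chain[t] = min(chain[t], p)
        for t in genesets:
            null_ps[t][b] = chain[t]

    terms = sorted(genesets)
    emp = np.array([
        (1.0 + np.sum(null_ps[t] <= observed_p.get(t, 1.0))) / (n_resample + 1)
        for t in terms
    ])
    fdr = multipletests(emp, method="fdr_bh")[1]
    rows = []
    for i, t in enumerate(terms):
        rows.append((
            t, observed_p.get(t, 1.0), float(np.median(null_ps[t])),
            float(emp[i]), float(fdr[i]), bool(fdr[i] < 0.05),
        ))
    return pd.DataFrame(
        rows, columns=["pathway", "observed_p", "null_median_p",
                       "empirical_p", "fdr", "significant"],
    )


def enrichment_score(
    stats_sorted: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    ``stats_sorted`` is the ranking statistic sorted descending; ``in_set``
    is a boolean mask over the same order.  Returns the maximum-deviation
    running-sum score (sign carries direction).
    """
    w = np.abs(stats_sorted) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = (~in_set).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    running = np.cumsum(hit_w / total_hit - (~in_set) / n_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    gene_stats: dict[str, float] | pd.Series,
    genesets: GeneSets,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a gene-permutation null.

    Weight exponent 1; NES = ES / mean(|null ES| of the same sign); p is
    two-sided with the +1 correction; FDR is BH across the query sets.
    """
    s = pd.Series(gene_stats).astype(float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    order = s.sort_values(ascending=False)
    genes = order.index.to_numpy()
    vals = order.to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    for term in sorted(genesets):
        members = genesets[term] & set(genes)
        if len(members) < 2:
            raise ValueError(f"gene set {term} has fewer than 2 ranked genes")
        mask = np.isin(genes, sorted(members))
        es = enrichment_score(vals, mask)
        m = mask.sum()
        null = np.empty(n_perm)
        for b in range(n_perm):
            rmask = np.zeros(len(genes), dtype=bool)
            rmask[rng.choice(len(genes), size=m, replace=False)] = True
            null[b] = enrichment_score(vals, rmask)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        rows.append((term, es, nes, p, m))
    out = pd.DataFrame(rows, columns=["term", "es", "nes", "p", "size"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
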