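"""Shape-based sample clustering, simplified negative-binomial differential
expression, and rank-based TF/module activity scores.

The DE test is a deliberately simple NB Wald test standing in for the
off-the-shelf packages a full study would use: median-of-ratios size
factors, pooled method-of-moments dispersion, log2 fold change of
normalized group means with a 0.5 pseudo-count, delta-method standard
error, and BH FDR.  Activity scores convert a gene-level signed statistic
to normal scores and sum them over regulon targets (sign-flipping repressed
targets), giving an analytic N(0,1) null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .enrichment import Regulons

log = logging.getLogger(__name__)


def cluster_shapes(
    medians: pd.DataFrame,
    k: int = 3,
    restarts: int = 50,
    seed: int = 0,
) -> pd.Series:
    """k-means on z-scored shape-feature medians; best of ``restarts`` runs."""
    if k > len(medians):
        raise ValueError("k exceeds number of rows")
    x = medians.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(z)
    return pd.Series(labels, index=medians.index, name="cluster")


def filter_counts(
    counts: pd.DataFrame,
    coding: set[str] | None = None,
    cpm_min: float = 0.5,
    min_samples: int = 8,
) -> pd.DataFrame:
    """Keep coding genes with CPM > cpm_min in at least ``min_samples``."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm > cpm_min).sum(axis=1) >= min_samples
    keep = pd.Series(keep, index=counts.index)
    if coding is not None:
        keep &= counts.index.isin(coding)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    ok = np.isfinite(logx).all(axis=1)
    if not ok.any():
        raise ValueError("no gene expressed in every sample")
    ref = logx[ok].mean(axis=1)
    sf = np.exp(np.median(logx[ok] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def nb_differential_expression(
    counts: pd.DataFrame,
    group_of_interest: list[str],
    rest: list[str],
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Simplified NB Wald test of ``group_of_interest`` vs ``rest``.

    Columns: gene, base_mean, log2fc, se, wald_z, p, fdr.  log2fc uses the
    group of interest as numerator.
    """
    if len(group_of_interest) < 2 or len(rest) < 2:
        raise ValueError("each side needs at least 2 samples")
    sub = counts[list(group_of_interest) + list(rest)]
    if (sub.sum(axis=0) == 0).any():
        raise ValueError("a sample has an all-zero library")
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    n1, n2 = len(group_of_interest), len(rest)
    a = norm[:, :n1]
    b = norm[:, n1:]

    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.mean(axis=1)
    pc = 0.5
    log2fc = np.log2(m1 + pc) - np.log2(m2 + pc)

    # pooled method-of-moments dispersion from within-group moments
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    pooled_mean = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean ** 2
    alpha = np.nan_to_num(alpha, nan=dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    # delta-method SE of log2 ratio of group means under NB(mu, alpha)
    def var_mean(mu, n):
        return (mu + alpha * mu ** 2) / n

    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mean(m1, n1) / np.maximum(m1 + pc, pc) ** 2 / ln2sq
        + var_mean(m2, n2) / np.maximum(m2 + pc, pc) ** 2 / ln2sq
    )
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    p = 2 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": sub.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p": p,
            "fdr": fdr,
        }
    ).set_index("gene")


def regulon_activity(
    gene_stats: dict[str, float] | pd.Series,
    regulons: Regulons,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Signed-rank regulon activity NES from a gene-level statistic.

    Gene statistics are mapped to normal scores via rank quantiles; for each
    regulon, ``NES = sum(mode_i * z_i) / sqrt(n)`` over its targets with
    mode +1 for activated/unknown and -1 for repressed targets; p is the
    two-sided standard-normal tail, FDR is BH across regulons.
    """
    s = pd.Series(gene_stats).astype(float)
    if len(s) < 50:
        raise ValueError("need statistics for at least 50 genes")
    ranks = stats.rankdata(s.to_numpy())
    zscores = pd.Series(
        stats.norm.ppf(ranks / (len(s) + 1.0)), index=s.index
    )
    rows = []
    for tf, sets in regulons.items():
        modes: dict[str, float] = {}
        for g in sets.get("activated", set()) | sets.get("unknown", set()):
            modes[g] = 1.0
        for g in sets.get("repressed", set()):
            modes[g] = -1.0
        hits = [g for g in modes if g in zscores.index]
        if len(hits) < min_overlap:
            log.info("regulon %s overlaps <%d genes; skipped", tf, min_overlap)
            continue
        nes = sum(modes[g] * zscores[g] for g in hits) / np.sqrt(len(hits))
        p = 2 * stats.norm.sf(abs(nes))
        rows.append((tf, float(nes), float(p), len(hits)))
    out = pd.DataFrame(rows, columns=["name", "nes", "p", "n_targets"])
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out.set_index("name")


def module_activity(
    gene_stats: dict[str, float] | pd.Series,
    modules: dict[str, list[str]],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Module activity: regulon activity with every member mode +1."""
    regs = {m: {"activated": set(g), "repressed": set(), "unknown": set()}
            for m, g in modules.items()}
    return regulon_activity(gene_stats, regs, min_overlap)


def kendall_activity_correlation(
    module_nes: pd.DataFrame,
    tf_nes: dict[str, pd.DataFrame],
    sig_alpha: float = 0.05,
    min_samples: int = 8,
) -> pd.DataFrame:
    """Kendall tau-b between module activity and each TF's activity.

    ``module_nes`` has columns nes and fdr indexed by sample; ``tf_nes``
    maps TF name to a same-shaped frame.  Samples are kept only when both
    activities pass ``fdr < sig_alpha``; TFs with fewer than ``min_samples``
    surviving samples are reported NA with a reason.  FDR is BH across the
    testable TFs.
    """
    rows = []
    for tf, frame in tf_nes.items():
        common = module_nes.index.intersection(frame.index)
        both = (
            (module_nes.loc[common, "fdr"] < sig_alpha)
            & (frame.loc[common, "fdr"] < sig_alpha)
        )
        kept = common[both]
        if len(kept) < min_samples:
            rows.append((tf, np.nan, np.nan, len(kept),
                         "insufficient significant samples"))
            continue
        tau, p = stats.kendalltau(
            module_nes.loc[kept, "nes"], frame.loc[kept, "nes"]
        )
        rows.append((tf, float(tau), float(p), len(kept), ""))
    out = pd.DataFrame(rows, columns=["tf", "tau", "p", "n", "note"])
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"],
                                           method="fdr_bh")[1]
    return out.set_index("tf")


def ks_group_difference(
    values: pd.Series, groups: pd.Series, min_group: int = 5
) -> pd.DataFrame:
    """Two-sample KS test between every pair of groups."""
    labels = sorted(groups.dropna().unique())
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = values[groups == labels[i]].dropna()
            b = values[groups == labels[j]].dropna()
            if len(a) < min_group or len(b) < min_group:
                raise ValueError(
                    f"groups {labels[i]}/{labels[j]} below {min_group} samples"
                )
            d, p = stats.ks_2samp(a, b)
            rows.append((labels[i], labels[j], float(d), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "D", "p"])


def anova_shape(
    per_cell: pd.DataFrame,
    clusters: pd.Series,
    features: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One-way ANOVA per shape feature plus Tukey HSD pairwise tables.

    ``clusters`` is indexed like ``per_cell`` rows (or by a "line" column
    already merged in).  Returns (anova table, feature -> Tukey table).
    """
    labels = clusters.loc[per_cell.index]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    if features is None:
        features = [c for c in per_cell.columns
                    if np.issubdtype(per_cell[c].dtype, np.number)]
    anova_rows = []
    tukey: dict[str, pd.DataFrame] = {}
    for feat in features:
        groups = [per_cell.loc[labels == lab, feat].to_numpy()
                  for lab in sorted(labels.unique())]
        if any(len(g) < 2 for g in groups):
            raise ValueError("each cluster needs at least 2 cells")
        if all(np.var(g) == 0 for g in groups):
            log.warning("feature %s has zero within-group variance", feat)
        f, p = stats.f_oneway(*groups)
        anova_rows.append((feat, float(f), float(p)))
        res = pairwise_tukeyhsd(per_cell[feat].to_numpy(),
                                labels.astype(str).to_numpy())
        tukey[feat] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return pd.DataFrame(anova_rows, columns=["feature", "F", "p"]), tukey
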