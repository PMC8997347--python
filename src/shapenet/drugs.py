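"""Drug-perturbation validation of the assembled network.

Kinase inhibitors are filtered to narrow-spectrum profiles (binding class 1,
at most five targets).  A drug's influence on the network combines the
PageRank centrality of its in-network targets with the Szymkiewicz-Simpson
overlap between target set K and node set N:

    S = [sum_{x in K&N} PR(x)] * |K&N| / min(|K|, |N|)

Validation statistics compare morphology log fold changes between drugs
targeting kinases inside versus outside the network (Welch t and KS per
feature) and correlate influence with per-drug mean absolute effect
(Spearman per feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class DrugProfile:
    drug: str
    targets: set[str]
    binding_classes: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.targets) > 5:
            raise ValueError("profiles are limited to 5 targets")


def filter_drug_targets(tas: pd.DataFrame) -> list[DrugProfile]:
    """Keep binding-class-1 pairs; drop drugs with more than five such targets."""
    required = {"drug", "target", "binding_class"}
    if not required <= set(tas.columns):
        raise ValueError(f"TAS table needs columns {sorted(required)}")
    keep = tas[tas["binding_class"] == 1]
    profiles = []
    for drug, grp in keep.groupby("drug"):
        targets = set(grp["target"])
        if not targets or len(targets) > 5:
            continue
        profiles.append(
            DrugProfile(str(drug), targets, {t: 1 for t in targets})
        )
    return sorted(profiles, key=lambda p: p.drug)


def average_dye_readings(a: pd.Series, b: pd.Series) -> pd.Series:
    """Small-spot counts: mean of the two dye-normalized readings."""
    return (a + b) / 2.0


def morphology_lfc(
    response: pd.DataFrame,
    control_drugs: tuple[str, ...] = ("control", "untreated", "DMSO"),
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell log10 fold change versus the batch control mean.

    ``response`` has columns cell_id, drug, batch and feature values on the
    raw scale; controls are rows whose drug is in ``control_drugs`` (pooled
    per batch).  Features whose batch-control mean is zero are masked (NaN)
    for that batch.
    """
    if feature_cols is None:
        feature_cols = [c for c in response.columns
                        if c not in ("cell_id", "drug", "batch")]
    out = response.copy()
    for batch, grp in response.groupby("batch"):
        ctrl = grp[grp["drug"].isin(control_drugs)]
        if ctrl.empty:
            raise ValueError(f"batch {batch} has no control cells")
        means = ctrl[feature_cols].mean()
        rows = out["batch"] == batch
        for f in feature_cols:
            if means[f] == 0:
                log.warning("batch %s feature %s control mean 0; masked",
                            batch, f)
                out.loc[rows, f] = np.nan
            else:
                out.loc[rows, f] = np.log10(
                    response.loc[rows, f] / means[f]
                )
    return out


def pagerank_centrality(
    net: nx.DiGraph, damping: float = 0.85
) -> pd.Series:
    """PageRank on the undirected view with |weight| edge weights."""
    und = nx.Graph()
    und.add_nodes_from(net.nodes())
    for a, b, d in net.edges(data=True):
        w = abs(d.get("weight", 1.0))
        if und.has_edge(a, b):
            und[a][b]["weight"] = max(und[a][b]["weight"], w)
        else:
            und.add_edge(a, b, weight=w)
    pr = nx.pagerank(und, alpha=damping, weight="weight",
                     tol=1e-14, max_iter=1000)
    return pd.Series(pr).sort_index()


def influence_score(
    profile: DrugProfile,
    net: nx.DiGraph,
    pagerank: pd.Series | None = None,
) -> float:
    """Network influence of a drug: summed target PageRank times overlap."""
    if len(net) == 0:
        raise ValueError("empty network")
    if pagerank is None:
        pagerank = pagerank_centrality(net)
    inside = profile.targets & set(net.nodes())
    if not inside:
        return 0.0
    overlap = len(inside) / min(len(profile.targets), len(net))
    return float(sum(pagerank[t] for t in inside) * overlap)


def _drug_lfc_table(
    lfcs: pd.DataFrame, feature_cols: list[str]
) -> pd.DataFrame:
    """Per-drug mean absolute LFC per feature (controls excluded)."""
    treated = lfcs[~lfcs["drug"].isin(("control", "untreated", "DMSO"))]
    return treated.groupby("drug")[feature_cols].apply(
        lambda g: g.abs().mean()
    )


def compare_in_vs_out(
    lfcs: pd.DataFrame,
    profiles: list[DrugProfile],
    net: nx.DiGraph,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Welch t and KS tests of |LFC| for in-network vs out-network drugs.

    A drug is in-network when at least one filtered target is a network
    node.  Cells of all drugs in a group are pooled per feature.  Returns
    one row per feature; with fewer than two drugs on either side the tests
    are NA with a reason.
    """
    if feature_cols is None:
        feature_cols = [c for c in lfcs.columns
                        if c not in ("cell_id", "drug", "batch")]
    nodes = set(net.nodes())
    in_drugs = {p.drug for p in profiles if p.targets & nodes}
    out_drugs = {p.drug for p in profiles} - in_drugs
    rows = []
    for f in feature_cols:
        a = lfcs.loc[lfcs["drug"].isin(in_drugs), f].abs().dropna()
        b = lfcs.loc[lfcs["drug"].isin(out_drugs), f].abs().dropna()
        if len(in_drugs) < 2 or len(out_drugs) < 2 or a.empty or b.empty:
            rows.append((f, np.nan, np.nan, np.nan, np.nan,
                         "fewer than 2 drugs in a group"))
            continue
        t, tp = stats.ttest_ind(a, b, equal_var=False)
        d, kp = stats.ks_2samp(a, b)
        rows.append((f, float(t), float(tp), float(d), float(kp), ""))
    return pd.DataFrame(
        rows, columns=["feature", "welch_t", "welch_p", "ks_D", "ks_p", "note"]
    )


def correlate_influence(
    lfcs: pd.DataFrame,
    scores: dict[str, float],
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of influence score vs per-drug mean |LFC|."""
    if feature_cols is None:
        feature_cols = [c for c in lfcs.columns
                        if c not in ("cell_id", "drug", "batch")]
    per_drug = _drug_lfc_table(lfcs, feature_cols)
    drugs = [d for d in per_drug.index if d in scores]
    if len(drugs) < 5:
        raise ValueError("need at least 5 drugs with influence scores")
    s = np.array([scores[d] for d in drugs])
    rows = []
    for f in feature_cols:
        y = per_drug.loc[drugs, f].to_numpy()
        if np.all(s == s[0]) or np.all(y == y[0]):
            rows.append((f, np.nan, np.nan, "constant input"))
            continue
        rho, p = stats.spearmanr(s, y)
        rows.append((f, float(rho), float(p), ""))
    return pd.DataFrame(rows, columns=["feature", "rho", "p", "note"])
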