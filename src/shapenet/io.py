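"""Tab-separated file dialects used across the pipeline.

All formats are plain TSV with a header row; lines starting with '#' are
comments.  Gene sets and regulons use GMT (name, description, members) with
regulon direction encoded by a name suffix: ``TF+`` activated, ``TF-``
repressed, ``TF?`` unknown sign.  Malformed rows are reported with their
line number; duplicate gene identifiers are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    pass


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: genes as rows, samples as columns."""
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids: {dups[:5]}")
    return df


write_expression = write_matrix


def read_shape(path) -> pd.DataFrame:
    """Shape-feature TSV: samples (or cells) as rows, features as columns."""
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate sample ids in shape table")
    return df


def write_shape(df: pd.DataFrame, path) -> None:
    write_matrix(df, path, index_label="sample")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT needs name, "
                                  "description and >=1 member")
            name = parts[0]
            if name in out:
                raise FormatError(f"{path}:{ln}: duplicate set name {name}")
            out[name] = {p for p in parts[2:] if p}
            if not out[name]:
                raise FormatError(f"{path}:{ln}: empty member list")
    return out


def write_gmt(sets: dict[str, set[str]], path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def regulons_to_gmt(regulons: dict[str, dict[str, set[str]]]) -> dict[str, set[str]]:
    out = {}
    for tf, sets in regulons.items():
        for suffix, key in (("+", "activated"), ("-", "repressed"),
                            ("?", "unknown")):
            if sets.get(key):
                out[f"{tf}{suffix}"] = set(sets[key])
    return out


def gmt_to_regulons(sets: dict[str, set[str]]) -> dict[str, dict[str, set[str]]]:
    out: dict[str, dict[str, set[str]]] = {}
    key = {"+": "activated", "-": "repressed", "?": "unknown"}
    for name, members in sets.items():
        suffix = name[-1]
        if suffix not in key:
            raise FormatError(f"regulon set name {name!r} lacks a +/-/? suffix")
        tf = name[:-1]
        entry = out.setdefault(
            tf, {"activated": set(), "repressed": set(), "unknown": set()}
        )
        entry[key[suffix]] |= members
    return out


def read_edge_list(path) -> pd.DataFrame:
    """Signed edge list TSV: source, target, sign, n_sources."""
    df = _read_tsv(path)
    required = ["source", "target", "sign", "n_sources"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"edge list must start with columns {required}")
    bad = ~df["sign"].isin([1, -1])
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        raise FormatError(f"invalid sign at line(s) {lines[:5]}")
    if (df["n_sources"] < 1).any():
        raise FormatError("n_sources must be >= 1")
    return df


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ontology(parents_path, annotations_path):
    """Parent-child TSV (child, parent; root has empty parent) plus
    two-column annotation TSV (gene, term)."""
    pdf = _read_tsv(parents_path, dtype=str, keep_default_na=False)
    if list(pdf.columns[:2]) != ["child", "parent"]:
        raise FormatError("ontology file needs columns child, parent")
    parents: dict[str, set[str]] = {}
    for _, row in pdf.iterrows():
        parents.setdefault(row["child"], set())
        if row["parent"]:
            parents[row["child"]].add(row["parent"])
            parents.setdefault(row["parent"], set())
    adf = _read_tsv(annotations_path, dtype=str)
    if list(adf.columns[:2]) != ["gene", "term"]:
        raise FormatError("annotation file needs columns gene, term")
    annotations: dict[str, set[str]] = {}
    for _, row in adf.iterrows():
        annotations.setdefault(row["gene"], set()).add(row["term"])
    return parents, annotations


def write_ontology(parents: dict[str, set[str]],
                   annotations: dict[str, set[str]],
                   parents_path, annotations_path) -> None:
    rows = []
    for child in sorted(parents):
        ps = sorted(parents[child])
        if not ps:
            rows.append((child, ""))
        for p in ps:
            rows.append((child, p))
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(
        parents_path, sep="\t", index=False
    )
    arows = [(g, t) for g in sorted(annotations)
             for t in sorted(annotations[g])]
    pd.DataFrame(arows, columns=["gene", "term"]).to_csv(
        annotations_path, sep="\t", index=False
    )


def read_drug_targets(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if list(df.columns[:3]) != ["drug", "target", "binding_class"]:
        raise FormatError("drug table needs columns drug, target, binding_class")
    return df


def read_response(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("cell_id", "drug", "batch"):
        if col not in df.columns:
            raise FormatError(f"response table missing column {col}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_network(net, edge_path, node_path,
                  prizes: dict[str, float] | None = None) -> None:
    rows = [
        (a, b, d.get("sign", 1), d.get("weight", 1.0), d.get("origin", ""),
         d.get("similarity", ""))
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign", "weight",
                                "origin", "similarity"]).to_csv(
        edge_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    prizes = prizes or {}
    nrows = [
        (v, d.get("kind", "protein"), prizes.get(v, 0.0))
        for v, d in sorted(net.nodes(data=True))
    ]
    pd.DataFrame(nrows, columns=["node", "kind", "prize"]).to_csv(
        node_path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_network(edge_path, node_path):
    import networkx as nx

    edges = _read_tsv(edge_path)
    nodes = _read_tsv(node_path)
    net = nx.DiGraph()
    for _, row in nodes.iterrows():
        net.add_node(row["node"], kind=row["kind"])
    for _, row in edges.iterrows():
        attrs = dict(sign=int(row["sign"]), weight=float(row["weight"]),
                     origin=row["origin"])
        if pd.notna(row.get("similarity")) and row.get("similarity") != "":
            attrs["similarity"] = float(row["similarity"])
        net.add_edge(row["source"], row["target"], **attrs)
    return net


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study defaults."""

    out_dir: str = "results"
    seed: int = 20220401
    # coexpression
    beta: int = 9
    min_module_size: int = 30
    cut_height: float = 0.9
    merge_corr: float = 0.85
    fpkm_min: float = 1.0
    n_perm: int = 1000
    # enrichment
    alpha_tf: float = 0.1
    n_rank_perm: int = 200
    n_resample: int = 1000
    # clustering / DE / activity
    k_clusters: int = 3
    kmeans_restarts: int = 50
    cpm_min: float = 0.5
    cpm_min_samples: int = 8
    activity_alpha: float = 0.05
    # assembly
    prize_value: float = 100.0
    prize_b: float = 1.0
    tree_w: float = 40.0
    hub_mu: float = 0.005
    cost_noise: float = 0.05
    pcsf_iterations: int = 30
    # propagation
    restart: float = 0.95
    n_rand: int = 10000
    rwr_alpha: float = 0.1
    rwr_mode: str = "positive"
    # flow
    flow_percentile: float = 99.0
    # synthetic-data overrides (names of SynthConfig fields)
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
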