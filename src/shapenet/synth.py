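"""Synthetic inputs with planted ground truth.

Every dataset the pipeline consumes — expression matrices, shape-feature
tables, a signed prior network, TF regulons, pathway gene sets, a term
ontology and a drug screen — can be generated here at desk scale, with the
planted structure recorded so downstream stages are testable end to end.

The expression generator uses a latent-factor model: each planted module is
driven by one factor, genes load on it with weight ``sqrt(within_module_corr)``
plus independent noise, and shape features are noisy copies of the factors at
configured correlation strengths.  Background genes are independent noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


DEFAULT_SEED = 20220401

#: morphology feature names used throughout (size, texture and contact
#: descriptors of cell and nucleus).
SHAPE_FEATURES = (
    "cell_area",
    "cell_perimeter",
    "nuclear_by_cyto_area",
    "ruffliness",
    "neighbor_fraction",
    "protrusion_area",
    "width_to_length",
    "nucleus_area",
    "nucleus_perimeter",
    "compactness",
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real study's structure at reduced scale: a handful
    of coexpression modules of 30-50 genes across 100 samples, shape
    features correlated with the module factors at strengths up to 0.8, a
    scale-free-ish signed prior network whose nodes overlap the gene
    universe, regulons half of which are planted inside modules, and a drug
    screen whose morphological effects grow with network influence.
    """

    n_background_genes: int = 200
    module_sizes: list[int] = field(default_factory=lambda: [50, 40, 35, 30])
    n_samples: int = 100
    shape_feature_count: int = 10
    eigengene_shape_corr: list[float] = field(
        default_factory=lambda: [0.8, -0.8, 0.7, 0.6]
    )
    within_module_corr: float = 0.8
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    planted_lfc: float = 1.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    network_nodes: int = 400
    network_edge_prob: float | None = None
    attachment_m: int = 2
    n_regulons: int = 16
    regulon_size: int = 15
    positive_control_frac: float = 0.5
    unknown_sign_frac: float = 0.2
    ontology_depth: int = 4
    ontology_branching: int = 3
    n_pathways: int = 8
    pathway_size: int = 30
    n_drugs: int = 40
    # mean |log10 FC| of a drug = slope x network influence; influence is
    # O(1/network size), so 10 puts central-target effects near 0.2-0.4
    drug_effect_slope: float = 10.0
    drug_noise_sd: float = 0.05
    cells_per_drug: int = 20
    rng_seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        counts = dict(
            n_background_genes=self.n_background_genes,
            n_samples=self.n_samples,
            shape_feature_count=self.shape_feature_count,
            network_nodes=self.network_nodes,
            n_regulons=self.n_regulons,
            regulon_size=self.regulon_size,
            ontology_depth=self.ontology_depth,
            ontology_branching=self.ontology_branching,
            n_drugs=self.n_drugs,
        )
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if not 0 < self.within_module_corr <= 1:
            raise ValueError("within_module_corr must lie in (0, 1]")
        for r in self.eigengene_shape_corr:
            if not -1 <= r <= 1:
                raise ValueError(f"shape correlation target {r} outside [-1, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.nb_mean <= 0:
            raise ValueError("nb_mean must be positive")


@dataclass
class GroundTruth:
    """Planted structure recorded by the generators."""

    module_assignment: dict[str, str] = field(default_factory=dict)
    module_factors: pd.DataFrame | None = None
    true_tf_activity: dict[str, float] = field(default_factory=dict)
    true_de_genes: dict[str, int] = field(default_factory=dict)
    drug_true_influence: dict[str, float] = field(default_factory=dict)

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.module_assignment.items() if m == label]

    @property
    def module_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.module_assignment.values():
            if m != "unassigned":
                seen.setdefault(m, None)
        return list(seen)


def gene_names(config: SynthConfig) -> list[str]:
    n = sum(config.module_sizes) + config.n_background_genes
    return [f"G{i:04d}" for i in range(n)]


def tf_names(config: SynthConfig) -> list[str]:
    return [f"TF{i:02d}" for i in range(config.n_regulons)]


def gen_expression(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate an FPKM-like expression matrix and shape-feature table.

    Returns ``(expression, shape, truth)``: expression is genes x samples on
    a positive FPKM-like scale (analysis log2-transforms it), shape is
    samples x shape_feature_count, and truth records the module assignment
    and the latent factors.

    Raises ``ValueError`` for infeasible correlation targets.
    """
    if config.n_samples < 4:
        raise ValueError("need at least 4 samples")
    n_modules = len(config.module_sizes)
    if len(config.eigengene_shape_corr) > config.shape_feature_count:
        raise ValueError("more correlation targets than shape features")

    rng = np.random.default_rng(config.rng_seed)
    n = config.n_samples
    factors = rng.standard_normal((n, n_modules))
    factors = (factors - factors.mean(0)) / factors.std(0)

    rho = config.within_module_corr
    load = math.sqrt(rho)
    noise_sd = math.sqrt(1 - rho)

    rows = []
    names = gene_names(config)
    assignment: dict[str, str] = {}
    gi = 0
    labels = [f"M{k + 1}" for k in range(n_modules)]
    for k, size in enumerate(config.module_sizes):
        for _ in range(size):
            z = load * factors[:, k] + noise_sd * rng.standard_normal(n)
            rows.append(z)
            assignment[names[gi]] = labels[k]
            gi += 1
    for _ in range(config.n_background_genes):
        rows.append(rng.standard_normal(n))
        assignment[names[gi]] = "unassigned"
        gi += 1

    # positive FPKM-like scale; log2 recovers the latent z up to an offset
    log2_expr = 5.0 + np.asarray(rows)
    expr = pd.DataFrame(
        np.power(2.0, log2_expr),
        index=pd.Index(names, name="gene"),
        columns=[f"S{j:03d}" for j in range(n)],
    )

    features = list(SHAPE_FEATURES[: config.shape_feature_count])
    while len(features) < config.shape_feature_count:
        features.append(f"feature_{len(features)}")
    shape = np.empty((n, config.shape_feature_count))
    for j in range(config.shape_feature_count):
        if j < len(config.eigengene_shape_corr) and j < n_modules:
            r = config.eigengene_shape_corr[j]
            if abs(r) > 1:
                raise ValueError(f"infeasible correlation target {r}")
            shape[:, j] = r * factors[:, j] + math.sqrt(1 - r * r) * (
                rng.standard_normal(n)
            )
        else:
            shape[:, j] = rng.standard_normal(n)
    shape_df = pd.DataFrame(
        shape, index=pd.Index(expr.columns, name="sample"), columns=features
    )

    truth = GroundTruth(
        module_assignment=assignment,
        module_factors=pd.DataFrame(factors, index=expr.columns, columns=labels),
    )
    return expr, shape_df, truth


def expand_shape_per_cell(
    shape: pd.DataFrame,
    cells_per_line: int = 50,
    noise_sd: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Per-cell expansion of line-level shape medians (Gaussian around the
    median) for ANOVA-style tests."""
    rng = np.random.default_rng(seed)
    blocks = []
    for line, row in shape.iterrows():
        vals = row.values + noise_sd * rng.standard_normal(
            (cells_per_line, shape.shape[1])
        )
        block = pd.DataFrame(vals, columns=shape.columns)
        block.insert(0, "line", line)
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True)
    out.index = [f"cell{i:05d}" for i in range(len(out))]
    return out


def gen_counts(
    config: SynthConfig,
    groups: dict[str, str] | pd.Series,
    de_genes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial count matrix with planted fold changes.

    ``groups`` maps sample name to group label; the first group in sorted
    order is the "group of interest" whose planted DE genes have means
    shifted by ``2**planted_lfc``.  Library sizes vary uniformly within
    ``library_size_range``.  ``de_genes`` maps gene -> sign (+1 up in the
    group of interest, -1 down); by default the first two planted modules
    move coherently (one up, one down), keeping the regulons planted inside
    them consistent with a signed TF activity.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab} has fewer than 2 samples")

    rng = np.random.default_rng(config.rng_seed + 1)
    names = gene_names(config)
    samples = list(groups.index)
    lib = rng.uniform(*config.library_size_range, size=len(samples))

    if de_genes is None:
        de_genes = {}
        offset = 0
        for k, size in enumerate(config.module_sizes[:2]):
            sign = 1 if k == 0 else -1
            for g in names[offset: offset + size]:
                de_genes[g] = sign
            offset += size
    truth = GroundTruth(true_de_genes=dict(de_genes))

    r = 1.0 / config.nb_dispersion
    counts = np.empty((len(names), len(samples)), dtype=np.int64)
    interest = labels[0]
    for i, g in enumerate(names):
        sign = de_genes.get(g, 0)
        for j, s in enumerate(samples):
            mu = config.nb_mean * lib[j]
            if sign and groups[s] == interest:
                mu *= 2.0 ** (config.planted_lfc * sign)
            p = r / (r + mu)
            counts[i, j] = rng.negative_binomial(r, p)
    return (
        pd.DataFrame(counts, index=pd.Index(names, name="gene"),
                     columns=samples),
        truth,
    )


def gen_prior_network(config: SynthConfig) -> pd.DataFrame:
    """Signed directed prior-knowledge edge list.

    Columns: source, target, sign (+1/-1), n_sources (1..25).  By default a
    preferential-attachment graph oriented hub -> spoke, giving heavy-tailed
    out-degree; set ``network_edge_prob`` for an Erdos-Renyi alternative.
    Node names are drawn from the gene universe plus the TF names so prizes,
    regulons and modules all live on the same graph.
    """
    if config.network_nodes < 2:
        raise ValueError("network_nodes must be >= 2")
    rng = np.random.default_rng(config.rng_seed + 2)

    tfs = tf_names(config)
    genes = gene_names(config)
    n_extra = max(config.network_nodes - len(tfs), 0)
    # keep planted-module genes in the network preferentially
    module_genes = genes[: sum(config.module_sizes)]
    pool = module_genes + genes[sum(config.module_sizes):]
    nodes = tfs + pool[:n_extra]
    n = len(nodes)

    edges: list[tuple[int, int]] = []
    if config.network_edge_prob is not None:
        p = config.network_edge_prob
        if p > 0:
            mask = rng.random((n, n)) < p
            np.fill_diagonal(mask, False)
            src, dst = np.nonzero(mask)
            edges = list(zip(src.tolist(), dst.tolist()))
    else:
        m = config.attachment_m
        degree = np.zeros(n)
        order = rng.permutation(n)
        seed_nodes = order[: m + 1]
        for i in range(len(seed_nodes) - 1):
            edges.append((int(seed_nodes[i]), int(seed_nodes[i + 1])))
            degree[seed_nodes[i]] += 1
            degree[seed_nodes[i + 1]] += 1
        for idx in order[m + 1:]:
            w = degree + 1e-9
            w[idx] = 0
            w = w / w.sum()
            targets = rng.choice(n, size=min(m, int((degree > 0).sum())),
                                 replace=False, p=w)
            for t in targets:
                edges.append((int(t), int(idx)))  # hub -> new node
                degree[t] += 1
                degree[idx] += 1

    seen = set()
    rows = []
    for s, t in edges:
        if s == t or (s, t) in seen:
            continue
        seen.add((s, t))
        sign = 1 if rng.random() < 0.7 else -1
        # truncated geometric citation counts, heavy at 1
        ns = int(min(rng.geometric(0.35), 25))
        rows.append((nodes[s], nodes[t], sign, ns))
    return pd.DataFrame(rows, columns=["source", "target", "sign", "n_sources"])


def gen_regulons(
    config: SynthConfig, truth: GroundTruth
) -> tuple[dict[str, dict[str, set[str]]], GroundTruth]:
    """TF regulons, a configured fraction planted inside modules.

    Returns ``(regulons, truth)`` where regulons maps TF ->
    {"activated": set, "repressed": set, "unknown": set} and truth gains
    ``true_tf_activity`` for the positive-control TFs (sign +1 for activating
    regulons planted in a module, -1 for repressing).
    """
    genes = gene_names(config)
    if config.regulon_size > len(genes):
        raise ValueError("regulon_size exceeds gene universe")
    rng = np.random.default_rng(config.rng_seed + 3)
    labels = truth.module_labels
    regulons: dict[str, dict[str, set[str]]] = {}
    n_pos = int(round(config.positive_control_frac * config.n_regulons))
    for i, tf in enumerate(tf_names(config)):
        if i < n_pos and labels:
            mod = labels[i % len(labels)]
            members = truth.module_genes(mod)
            k = min(config.regulon_size, len(members))
            targets = list(rng.choice(members, size=k, replace=False))
            activity = 1.0 if i % 2 == 0 else -1.0
        else:
            targets = list(rng.choice(genes, size=config.regulon_size,
                                      replace=False))
            activity = 0.0
        n_unknown = int(round(config.unknown_sign_frac * len(targets)))
        unknown = set(targets[:n_unknown])
        signed = targets[n_unknown:]
        if activity >= 0:
            activated, repressed = set(signed), set()
        else:
            activated, repressed = set(), set(signed)
        regulons[tf] = {
            "activated": activated,
            "repressed": repressed,
            "unknown": unknown,
        }
        if activity != 0.0:
            truth.true_tf_activity[tf] = activity
    return regulons, truth


def gen_genesets(config: SynthConfig) -> dict[str, set[str]]:
    """Named pathway gene sets partitioning part of the universe.

    Each pathway carries a disjoint slice of genes.  TF membership is
    deliberately uneven, as in curated pathway collections: the first two
    pathways are TF-rich (splitting the first half of the TF roster, which
    holds the planted-regulon TFs), the rest carry a single TF each.  A set
    of TFs recovered from module enrichment therefore concentrates in the
    TF-rich pathways.
    """
    genes = gene_names(config)
    tfs = tf_names(config)
    rng = np.random.default_rng(config.rng_seed + 4)
    perm = list(rng.permutation(genes))
    half = max(len(tfs) // 2, 1)
    rich = [set(tfs[: (half + 1) // 2]), set(tfs[(half + 1) // 2: half])]
    out: dict[str, set[str]] = {}
    for i in range(config.n_pathways):
        lo = i * config.pathway_size
        members = set(perm[lo: lo + config.pathway_size])
        if i < 2:
            members |= rich[i]
        else:
            members.add(tfs[(half + i - 2) % len(tfs)])
        out[f"PW{i:02d}"] = members
    return out


def gen_ontology(
    config: SynthConfig,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Rooted ontology DAG plus gene annotations.

    Returns ``(parents, annotations)``: parents maps term -> set of parent
    terms (root has none), annotations maps gene -> set of directly
    annotated terms (every gene gets at least one, biased toward deep
    terms).  A tree of ``ontology_branching ** d`` terms per depth d, plus a
    few cross-links to make it a genuine DAG.
    """
    b, depth = config.ontology_branching, config.ontology_depth
    rng = np.random.default_rng(config.rng_seed + 5)
    parents: dict[str, set[str]] = {"T:root": set()}
    levels: list[list[str]] = [["T:root"]]
    tid = 0
    for d in range(1, depth + 1):
        level = []
        for parent in levels[d - 1]:
            for _ in range(b):
                term = f"T:{tid:04d}"
                tid += 1
                parents[term] = {parent}
                level.append(term)
        levels.append(level)
    # sparse cross-links between non-adjacent branches
    if depth >= 2:
        deep = levels[-1]
        mids = levels[1]
        for term in rng.choice(deep, size=max(1, len(deep) // 10),
                               replace=False):
            extra = str(rng.choice(mids))
            parents[term] = parents[term] | {extra}

    annotatable = [t for lvl in levels[1:] for t in lvl] or ["T:root"]
    annotations: dict[str, set[str]] = {}
    universe = gene_names(config) + tf_names(config)
    for g in universe:
        k = min(1 + int(rng.integers(0, 3)), len(annotatable))
        annotations[g] = set(rng.choice(annotatable, size=k, replace=False))
    if depth < 1 or not levels[1:]:
        annotations = {g: {"T:root"} for g in universe}
    return parents, annotations


def gen_drug_screen(
    network,
    config: SynthConfig,
    modeled_features: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Kinase-inhibitor screen over an assembled network.

    Each drug receives 1-5 binding-class-1 targets sampled inside or outside
    the network node set; per-cell morphology log10 fold changes are drawn
    with mean ``drug_effect_slope * influence`` on modeled features (zero on
    unmodeled features), where influence is the drug's network influence
    score computed on ``network``.  Control cells with zero mean effect are
    included per batch.

    Returns ``(targets, response_lfc, truth)``.
    """
    from .drugs import DrugProfile, influence_score

    protein_nodes = [
        n for n, d in network.nodes(data=True)
        if d.get("kind", "protein") == "protein"
    ]
    if not protein_nodes:
        raise ValueError("network has no protein nodes")
    rng = np.random.default_rng(config.rng_seed + 6)
    outside_pool = [f"K{i:03d}" for i in range(200)]

    features = list(SHAPE_FEATURES[: config.shape_feature_count])
    if modeled_features is None:
        modeled_features = features[: max(1, len(features) // 2)]
    modeled = [f in modeled_features for f in features]

    target_rows = []
    truth = GroundTruth()
    drug_targets: dict[str, list[str]] = {}
    for i in range(config.n_drugs):
        drug = f"D{i:03d}"
        k = int(rng.integers(1, 6))
        if i % 2 == 0:  # in-network drug
            targets = list(rng.choice(protein_nodes, size=min(k, len(protein_nodes)),
                                      replace=False))
        else:
            targets = list(rng.choice(outside_pool, size=k, replace=False))
        drug_targets[drug] = targets
        for t in targets:
            target_rows.append((drug, t, 1))
    targets_df = pd.DataFrame(target_rows,
                              columns=["drug", "target", "binding_class"])

    for drug, targets in drug_targets.items():
        prof = DrugProfile(drug=drug, targets=set(targets),
                           binding_classes={t: 1 for t in targets})
        truth.drug_true_influence[drug] = influence_score(prof, network)

    # raw-scale morphology values: baseline 100 scaled by 10**effect so the
    # downstream batch-control LFC derivation recovers the planted effect
    baseline = 100.0
    rows = []
    cid = 0
    for drug in list(drug_targets) + ["control"]:
        infl = truth.drug_true_influence.get(drug, 0.0)
        for _ in range(config.cells_per_drug):
            vals = []
            for f, is_mod in zip(features, modeled):
                mean = (config.drug_effect_slope * infl
                        if is_mod and drug != "control" else 0.0)
                effect = mean + config.drug_noise_sd * rng.standard_normal()
                vals.append(baseline * 10.0 ** effect)
            rows.append([f"cell{cid:05d}", drug, "batch1"] + vals)
            cid += 1
    response = pd.DataFrame(rows, columns=["cell_id", "drug", "batch"] + features)
    return targets_df, response, truth
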