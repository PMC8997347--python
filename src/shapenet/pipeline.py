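"""End-to-end pipeline driver.

Runs the seven analysis stages in order — coexpression, enrichment,
phenotype activity, network assembly, propagation, drug validation and
max-flow — over synthetic (or user-supplied) inputs, writing per-stage TSV
outputs plus a manifest echoing every parameter and seed.  Each stage reads
its inputs back from the files written by earlier stages, so a partially
complete results directory resumes where it left off.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, assembly, coexpression as coex, drugs, enrichment
from . import flow as flowmod
from . import io as sio
from . import propagation as prop
from . import synth

log = logging.getLogger(__name__)

STAGES = [
    "coexpression",
    "enrichment",
    "phenotype_activity",
    "network_assembly",
    "propagation",
    "drug_validation",
    "flow",
]

_STAGE_OUTPUTS = {
    "inputs": ["expression.tsv", "shape.tsv", "prior_edges.tsv",
               "regulons.gmt", "genesets.gmt", "ontology_parents.tsv",
               "ontology_annotations.tsv", "truth_modules.gmt"],
    "coexpression": ["modules.gmt", "eigengenes.tsv", "shape_corr_r.tsv",
                     "shape_corr_p.tsv", "shape_corr_pperm.tsv",
                     "shape_corr_sig.tsv"],
    "enrichment": ["regulon_module_enrichment.tsv",
                   "tf_pathway_enrichment.tsv", "pathway_null.tsv"],
    "phenotype_activity": ["clusters.tsv", "counts.tsv", "de.tsv",
                           "tf_activity.tsv", "module_activity.tsv"],
    "network_assembly": ["network_edges.tsv", "network_nodes.tsv",
                         "prizes.tsv"],
    "propagation": ["weighted_edges.tsv", "weighted_nodes.tsv", "rwr.tsv"],
    "drug_validation": ["drug_targets.tsv", "drug_lfc.tsv", "influence.tsv",
                        "in_vs_out.tsv", "influence_corr.tsv"],
    "flow": ["flow_edges.tsv", "flow_top.tsv", "flow_summary.json"],
}


def _done(out: Path, stage: str) -> bool:
    return all((out / f).exists() for f in _STAGE_OUTPUTS[stage])


def _synth_config(cfg: sio.PipelineConfig) -> synth.SynthConfig:
    return synth.SynthConfig(rng_seed=cfg.seed, **cfg.synth)


def _write_inputs(cfg: sio.PipelineConfig, out: Path) -> None:
    sc = _synth_config(cfg)
    expr, shape, truth = synth.gen_expression(sc)
    regulons, truth = synth.gen_regulons(sc, truth)
    genesets = synth.gen_genesets(sc)
    prior = synth.gen_prior_network(sc)
    parents, annotations = synth.gen_ontology(sc)

    sio.write_expression(expr, out / "expression.tsv")
    sio.write_shape(shape, out / "shape.tsv")
    sio.write_edge_list(prior, out / "prior_edges.tsv")
    sio.write_gmt(sio.regulons_to_gmt(regulons), out / "regulons.gmt")
    sio.write_gmt(genesets, out / "genesets.gmt")
    sio.write_ontology(parents, annotations, out / "ontology_parents.tsv",
                       out / "ontology_annotations.tsv")
    truth_mods = {m: set(truth.module_genes(m)) for m in truth.module_labels}
    sio.write_gmt(truth_mods, out / "truth_modules.gmt")
    (out / "truth_tf_activity.json").write_text(
        json.dumps(truth.true_tf_activity, sort_keys=True)
    )


def _stage_coexpression(cfg: sio.PipelineConfig, out: Path) -> None:
    expr = sio.read_expression(out / "expression.tsv")
    shape = sio.read_shape(out / "shape.tsv")
    filtered = coex.filter_genes(expr, None, cfg.fpkm_min)
    log2 = np.log2(filtered)
    params = coex.CoexpressionParams(cfg.beta, cfg.min_module_size,
                                     cfg.cut_height, cfg.merge_corr)
    adj = coex.adjacency(log2, params.beta)
    tom = coex.topological_overlap(adj)
    modules = coex.detect_modules(1 - tom, log2, params)
    corr = coex.correlate_modules_shape(
        modules.eigengenes, shape, n_perm=cfg.n_perm, seed=cfg.seed + 11
    )
    sio.write_gmt({m: set(g) for m, g in modules.modules.items()},
                  out / "modules.gmt")
    sio.write_matrix(modules.eigengenes, out / "eigengenes.tsv", "sample")
    sio.write_matrix(corr.pcc, out / "shape_corr_r.tsv", "module")
    sio.write_matrix(corr.p_student, out / "shape_corr_p.tsv", "module")
    sio.write_matrix(corr.p_perm, out / "shape_corr_pperm.tsv", "module")
    sio.write_matrix(corr.significant.astype(int),
                     out / "shape_corr_sig.tsv", "module")


def _universe(out: Path) -> set[str]:
    expr = sio.read_expression(out / "expression.tsv")
    return set(expr.index)


def _stage_enrichment(cfg: sio.PipelineConfig, out: Path) -> None:
    modules = {m: sorted(g) for m, g in sio.read_gmt(out / "modules.gmt").items()}
    regulons = sio.gmt_to_regulons(sio.read_gmt(out / "regulons.gmt"))
    genesets = sio.read_gmt(out / "genesets.gmt")
    universe = _universe(out)

    table = enrichment.regulon_module_enrichment(modules, regulons, universe,
                                                 cfg.alpha_tf)
    sio.write_table(table, out / "regulon_module_enrichment.tsv")

    tfs = enrichment.significant_tfs(table)
    tf_universe = set(regulons) | set().union(*genesets.values())
    results = enrichment.tf_pathway_enrichment(
        tfs, genesets, tf_universe, cfg.n_rank_perm, seed=cfg.seed + 12
    )
    sio.write_table(pd.DataFrame([
        (r.term, r.p, r.odds_ratio, r.combined_score, r.fdr,
         ",".join(sorted(r.overlap_genes)))
        for r in results
    ], columns=["term", "p", "odds_ratio", "combined_score", "fdr",
                "overlap"]), out / "tf_pathway_enrichment.tsv")

    observed = {r.term: r.p for r in results}
    null = enrichment.resampled_pathway_null(
        [len(g) for g in modules.values()], observed, regulons, genesets,
        universe, tf_universe, n_resample=cfg.n_resample,
        alpha_tf=cfg.alpha_tf, seed=cfg.seed + 13,
    )
    sio.write_table(null, out / "pathway_null.tsv")


def _stage_phenotype_activity(cfg: sio.PipelineConfig, out: Path) -> None:
    shape = sio.read_shape(out / "shape.tsv")
    clusters = activity.cluster_shapes(shape, cfg.k_clusters,
                                       cfg.kmeans_restarts, seed=cfg.seed + 14)
    sio.write_table(clusters.rename("cluster").reset_index()
                    .rename(columns={"index": "sample"}), out / "clusters.tsv")

    sc = _synth_config(cfg)
    counts, de_truth = synth.gen_counts(sc, clusters.astype(str))
    sio.write_matrix(counts, out / "counts.tsv")

    filtered = activity.filter_counts(
        counts, None, cfg.cpm_min,
        min_samples=min(cfg.cpm_min_samples, counts.shape[1] // 2),
    )
    interest = sorted(clusters.astype(str).unique())[0]
    goi = list(clusters.index[clusters.astype(str) == interest])
    rest = list(clusters.index[clusters.astype(str) != interest])
    de = activity.nb_differential_expression(filtered, goi, rest)
    sio.write_table(de.reset_index(), out / "de.tsv")

    regulons = sio.gmt_to_regulons(sio.read_gmt(out / "regulons.gmt"))
    stats_ = de["wald_z"]
    tf_act = activity.regulon_activity(stats_, regulons)
    sio.write_table(tf_act.reset_index(), out / "tf_activity.tsv")
    modules = {m: sorted(g) for m, g in sio.read_gmt(out / "modules.gmt").items()}
    mod_act = activity.module_activity(stats_, modules)
    sio.write_table(mod_act.reset_index(), out / "module_activity.tsv")


def _stage_network_assembly(cfg: sio.PipelineConfig, out: Path) -> None:
    prior = sio.read_edge_list(out / "prior_edges.tsv")
    regulons = sio.gmt_to_regulons(sio.read_gmt(out / "regulons.gmt"))
    genesets = sio.read_gmt(out / "genesets.gmt")
    universe = _universe(out)
    reg_table = pd.read_csv(out / "regulon_module_enrichment.tsv", sep="\t")
    tf_hits = enrichment.significant_tfs(reg_table)
    tf_act = pd.read_csv(out / "tf_activity.tsv", sep="\t", index_col=0)
    de_tf_hits = set(tf_act.index[tf_act["fdr"] < 0.1])
    pw = pd.read_csv(out / "tf_pathway_enrichment.tsv", sep="\t")
    enriched_pw = set(pw.loc[pw["p"] < 0.05, "term"])
    pathway_proteins = set()
    for term in enriched_pw:
        pathway_proteins |= genesets.get(term, set()) & universe

    params = assembly.PCSFParams(cfg.prize_value, cfg.prize_b, cfg.tree_w,
                                 cfg.hub_mu, cfg.cost_noise,
                                 cfg.pcsf_iterations, seed=cfg.seed + 15)
    g = assembly.prior_digraph(prior)
    prizes = assembly.collect_prizes(tf_hits, de_tf_hits, pathway_proteins,
                                     params, g)
    und = assembly.undirected_view(g)
    solution = assembly.pcsf_union(und, prizes, params)
    net = assembly.assemble_network(prior, solution)

    modules = {m: sorted(v) for m, v in sio.read_gmt(out / "modules.gmt").items()}
    corr = _load_shape_corr(out)
    net = assembly.add_supernodes(net, modules, regulons, corr, universe,
                                  alpha_tf=cfg.alpha_tf)
    sio.write_network(net, out / "network_edges.tsv",
                      out / "network_nodes.tsv", prizes)
    sio.write_table(
        pd.DataFrame(sorted(prizes.items()), columns=["node", "prize"]),
        out / "prizes.tsv",
    )


def _load_shape_corr(out: Path):
    return coex.ModuleShapeCorrelation(
        pcc=pd.read_csv(out / "shape_corr_r.tsv", sep="\t", index_col=0),
        p_student=pd.read_csv(out / "shape_corr_p.tsv", sep="\t", index_col=0),
        p_perm=pd.read_csv(out / "shape_corr_pperm.tsv", sep="\t", index_col=0),
        ci_low=None, ci_high=None,
        significant=pd.read_csv(out / "shape_corr_sig.tsv", sep="\t",
                                index_col=0).astype(bool),
    )


def _stage_propagation(cfg: sio.PipelineConfig, out: Path) -> None:
    net = sio.read_network(out / "network_edges.tsv", out / "network_nodes.tsv")
    parents, annotations = sio.read_ontology(out / "ontology_parents.tsv",
                                             out / "ontology_annotations.tsv")
    onto = prop.OntologyDAG(parents, annotations)
    weighted = prop.reweight_edges(net, onto)
    sio.write_network(weighted, out / "weighted_edges.tsv",
                      out / "weighted_nodes.tsv")

    tf_act = pd.read_csv(out / "tf_activity.tsv", sep="\t", index_col=0)
    in_net = tf_act.index.isin(weighted.nodes())
    sig = tf_act[in_net & (tf_act["p"] < cfg.activity_alpha)]
    if sig.empty:
        log.warning("no significantly active TFs in network; seeding with "
                    "the strongest in-network TF activities")
        sig = tf_act[in_net].reindex(
            tf_act[in_net]["nes"].abs().sort_values(ascending=False).index[:3]
        )
    frames = []
    for direction, sub in (("activated", sig[sig["nes"] > 0]),
                           ("deactivated", sig[sig["nes"] < 0])):
        if sub.empty:
            continue
        seeds = (sub["nes"].abs() / sub["nes"].abs().sum()).to_dict()
        res = prop.seed_significance(
            weighted, seeds, n_rand=cfg.n_rand, alpha=cfg.rwr_alpha,
            restart=cfg.restart, seed=cfg.seed + 16, mode=cfg.rwr_mode,
        )
        frames.append(pd.DataFrame({
            "node": res.probability.index,
            "direction": direction,
            "probability": res.probability.values,
            "p": res.p_value.values,
            "significant": res.significant.values,
        }))
    rwr_table = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["node", "direction",
                                            "probability", "p",
                                            "significant"]))
    sio.write_table(rwr_table, out / "rwr.tsv")


def _stage_drug_validation(cfg: sio.PipelineConfig, out: Path) -> None:
    net = sio.read_network(out / "weighted_edges.tsv",
                           out / "weighted_nodes.tsv")
    sc = _synth_config(cfg)
    sig = pd.read_csv(out / "shape_corr_sig.tsv", sep="\t", index_col=0)
    modeled = [f for f in sig.columns if sig[f].any()] or None
    targets, response, truth = synth.gen_drug_screen(net, sc, modeled)
    sio.write_table(targets, out / "drug_targets.tsv")

    lfcs = drugs.morphology_lfc(response)
    sio.write_table(lfcs, out / "drug_lfc.tsv")

    profiles = drugs.filter_drug_targets(targets)
    pr = drugs.pagerank_centrality(net)
    scores = {p.drug: drugs.influence_score(p, net, pr) for p in profiles}
    sio.write_table(
        pd.DataFrame(sorted(scores.items()), columns=["drug", "influence"]),
        out / "influence.tsv",
    )
    sio.write_table(drugs.compare_in_vs_out(lfcs, profiles, net),
                    out / "in_vs_out.tsv")
    sio.write_table(drugs.correlate_influence(lfcs, scores),
                    out / "influence_corr.tsv")


def _stage_flow(cfg: sio.PipelineConfig, out: Path) -> None:
    net = sio.read_network(out / "weighted_edges.tsv",
                           out / "weighted_nodes.tsv")
    gems = sorted(v for v, d in net.nodes(data=True)
                  if d.get("kind") == "gem_supernode")
    tf_act = pd.read_csv(out / "tf_activity.tsv", sep="\t", index_col=0)
    candidates = [t for t in
                  tf_act["nes"].abs().sort_values(ascending=False).index
                  if t in net]
    result = None
    for gem in gems:
        for tf in candidates:
            r = flowmod.max_flow(net, gem, tf)
            if r.value > 0:
                result = r
                break
        if result:
            break
    if result is None:
        log.warning("no positive-flow module/TF pair found")
        empty = pd.DataFrame(columns=["source", "target", "flow", "capacity"])
        sio.write_table(empty, out / "flow_edges.tsv")
        sio.write_table(empty, out / "flow_top.tsv")
        (out / "flow_summary.json").write_text(json.dumps(
            {"value": 0.0, "source": None, "sink": None}))
        return
    sio.write_table(result.edge_flow, out / "flow_edges.tsv")
    top = flowmod.top_flow_subnetwork(result, cfg.flow_percentile)
    sio.write_table(top, out / "flow_top.tsv")
    (out / "flow_summary.json").write_text(json.dumps(
        {"value": result.value, "source": result.source,
         "sink": result.sink}, sort_keys=True))


_STAGE_FN = {
    "coexpression": _stage_coexpression,
    "enrichment": _stage_enrichment,
    "phenotype_activity": _stage_phenotype_activity,
    "network_assembly": _stage_network_assembly,
    "propagation": _stage_propagation,
    "drug_validation": _stage_drug_validation,
    "flow": _stage_flow,
}


def run_pipeline(
    cfg: sio.PipelineConfig,
    resume: bool = True,
    stages: list[str] | None = None,
) -> Path:
    """Run the pipeline stages, writing outputs and a manifest to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not (resume and _done(out, "inputs")):
        _write_inputs(cfg, out)

    completed = []
    for stage in (STAGES if stages is None else stages):
        if resume and _done(out, stage):
            log.info("stage %s already complete; skipped", stage)
            completed.append({"stage": stage, "status": "skipped"})
            continue
        try:
            _STAGE_FN[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        completed.append({"stage": stage, "status": "completed"})

    manifest = {
        "seed": cfg.seed,
        "stages": completed,
        "parameters": {k: v for k, v in vars(cfg).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                  indent=1))
    return out
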