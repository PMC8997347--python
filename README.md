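# shapenet

Phenotype-specific signaling networks from paired gene-expression and
cell-morphology data.

Cell shape is both a readout and a driver of signaling state — in breast
cancer, morphological features such as cell–cell contact fraction and
ruffliness track progression toward an invasive phenotype. `shapenet`
implements a network-systems workflow that connects the two data types:

1. **Coexpression modules** — a signed weighted gene network
   (`a_ij = |(1 + cor(x_i, x_j))/2|^β`, β = 9) is built on log2 expression,
   converted to topological overlap, and clustered into modules (minimum
   size 30) summarized by eigengenes.
2. **Shape correlation** — module eigengenes are correlated with
   morphology features (Pearson, Student p, and a rank-matched permutation
   procedure over 1000 label shuffles); pairs with |r| > 0.5 and p < 0.05
   are phenotype-linked.
3. **Regulatory anchoring** — TF regulons overlapping the modules
   (one-sided Fisher, p < 0.1, activatory/inhibitory tested separately) and
   pathways enriched in those TFs (combined score −ln(p)·z, with a
   module-resampling bias null) define the prize nodes.
4. **Network assembly** — a prize-collecting Steiner forest over a signed
   prior interactome (edge costs from citation counts, prize 100, per-tree
   charge w = 40, hub penalty μ = 0.005, 30 noisy-cost iterations unioned)
   is augmented with module supernodes, phenotype nodes, and weight-1
   feedback edges.
5. **Propagation** — edges are reweighted by Resnik best-match-average
   semantic similarity (signed, scaled to [−1, 1]) and TF activities are
   diffused by random walk with restart (r = 0.95), with empirical
   significance from 10 000 seed randomizations.
6. **Drug validation** — narrow-spectrum kinase inhibitors (binding class
   1, ≤ 5 targets) are scored by
   `S = [Σ_{x∈K∩N} PR(x)] · |K∩N| / min(|K|, |N|)` and their morphology
   log-fold-changes tested in-network vs out (Welch/KS) and against S
   (Spearman).
7. **Max flow** — the route between a module supernode and a TF is
   extracted as the top-percentile flow-carrying edges under similarity
   capacities.

A synthetic-data module generates every input with planted ground truth
(modules, shape correlations, regulons, DE signs, drug effects), so the
entire pipeline is testable without external downloads.

## Worked example

Run the full pipeline on the default synthetic study and inspect it
(`examples/` has one narrative script per capability):

```sh
shapenet run-all --out results_demo --seed 20220401
python examples/01_modules_from_expression.py
```

The module-detection example prints:

```
expression matrix: 355 genes x 100 samples
detected modules: {'M1': 35, 'M2': 51, 'M3': 40, 'M4': 30}  (199 genes unassigned)
  planted M1 (50 genes): best-match Jaccard 0.98
  planted M2 (40 genes): best-match Jaccard 1.00
  planted M3 (35 genes): best-match Jaccard 1.00
  planted M4 (30 genes): best-match Jaccard 1.00
```

i.e. all four planted modules are recovered nearly exactly from the
355-gene, 100-sample matrix, with the independent background genes left
unassigned. Downstream, the assembly/propagation example reports a
~120-node network containing all prize nodes, with the module supernodes
among the highest-betweenness nodes and a few dozen proteins significantly
ranked by the restart walk; the drug example shows Welch p ≪ 0.01 and
Spearman ρ ≈ 0.9 between influence score and morphological effect for the
modeled features, and no signal for control features — the network is
phenotype-specific.

The CLI exposes each stage (`simulate`, `coexpress`, `enrich`, `cluster`,
`assemble`, `propagate`, `validate-drugs`, `flow`, `run-all`); a results
directory is resumable, every run writes a `manifest.json` echoing seeds
and parameters, and reruns with the same seed are byte-identical.

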