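# Methods

`shapenet` reconstructs a phenotype-specific signaling network from paired
bulk expression and cell-morphology data. This note records the models and
procedures implemented, the parameters that matter, what the synthetic data
emulate, and the numerical and design choices that were genuinely open.

## Coexpression modules

The gene–gene similarity is the signed weighted adjacency

    a_ij = |(1 + cor(x_i, x_j)) / 2|^beta

computed on log2-transformed expression with soft threshold `beta = 9`.
Taking the signed form literally, anti-correlated genes receive adjacency
near zero. Adjacency becomes the unsigned topological overlap

    t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and modules are detected on `1 − TOM` by average-linkage hierarchical
clustering with a static cut, a minimum module size of 30, and iterative
merging of modules whose eigengenes (first principal component of the
gene-standardized submatrix, unit variance, oriented along the mean
profile) correlate above `merge_corr = 0.85`.

**Static cut height.** The cut is a fraction of the maximum merge height.
On latent-factor data, background genes only merge near the very top of the
dendrogram (heights ≈ 0.99 of max) while planted modules complete merging
below ~0.7 of max; a cut at 0.9 separates the two regimes cleanly. Cuts at
0.995 of max lump background genes with modules — the default is therefore
0.9. A dynamic tree cut was deliberately not implemented; the static cut
plus eigengene merging is sufficient for the correlation structure this
pipeline targets and is far easier to reason about.

**Module–shape correlation.** Pearson r per (module eigengene, shape
feature) with the Student asymptotic p (`t = r sqrt((n−2)/(1−r²))`). The
multiple-testing procedure permutes the sample labels of the shape table
`B = 1000` times, recomputes the full |r| matrix each round, sorts its
entries, and compares each observed rank-k statistic with the permutation
distribution of rank-k statistics: `p_perm = (1 + #{null_k ≥ obs_k}) /
(B + 1)`, with a Wilson binomial interval on each p. Absolute correlations
are used in the ranking. The significance flag itself follows the
`|r| > 0.5 and Student p < 0.05` rule; the permutation p is reported
alongside. Note a property of the rank-matched construction: it is
calibrated under a complete null, but in a matrix that mixes strong true
correlations with null entries, the null entries are pushed down the
observed rank ladder and compared against more central null order
statistics, which inflates their rejection rate. Calibration checks
therefore use a fully null feature set.

**Jackknife.** Leave-one-sample-out re-detection; per reference module the
mean and min best-match Jaccard across folds.

## Enrichment

All over-representation tests are one-sided Fisher exact tests evaluated as
hypergeometric tail sums; the odds ratio uses the Haldane 0.5 correction on
empty cells; FDR control is Benjamini–Hochberg everywhere a correction is
applied. Regulon–module tests run separately for activatory and inhibitory
targets, with unknown-sign targets joined to both sides; a TF is retained
at p < 0.1. The test universe defaults to the genes surviving the
expression filter (configurable).

The pathway combined score is `−ln(p) × z`, where z is how far the
pathway's rank (by p) sits above its expected rank over 200 random query
sets of matched size (z floored at 0, so p = 1 always scores 0). The exact
z used by popular enrichment servers is not published; the explicit rank
permutation is this package's stand-in and is documented as such.

The pathway-bias null re-runs the module → TF → pathway chain on 1000
random gene modules matched to the observed module-size profile. Chains
with no TF enrichment contribute p = 1. The empirical pathway p is
`(1 + #{null ≤ observed}) / (B + 1)`, BH-adjusted.

Preranked gene-set enrichment uses the weighted Kolmogorov–Smirnov running
sum (weight exponent 1), a gene-permutation null, `NES = ES / mean(|null
ES| of the same sign)`, a two-sided p with the +1 correction, and BH FDR
across query sets.

## Phenotype activity

Samples are clustered on z-scored shape-feature medians by k-means
(k = 3, k-means++ with 50 restarts, best by within-cluster SS). A per-cell
expansion (Gaussian around line medians) supports one-way ANOVA with Tukey
HSD across clusters.

Differential expression is a deliberately simple NB Wald test standing in
for full GLM packages: median-of-ratios size factors; pooled within-group
method-of-moments dispersion floored at 1e−8; log2 fold change of
normalized group means with pseudo-count 0.5; delta-method standard error
`Var(log2 m) ≈ (m + α m²)/(n m² ln²2)`; two-sided normal p; BH FDR.
Shrinkage, outlier removal and independent filtering are intentionally
absent. At the calibration conditions used in the tests (7 vs 7, mean 100,
dispersion 0.05) the realized type-I error is ≈ 0.07 at p < 0.05 — mildly
anticonservative, as expected for moment-based dispersion at small n — and
power ≈ 0.95 for a planted log2 fold change of 1. One-vs-rest contrasts
with a single sample in the group of interest rely entirely on the pooled
dispersion and should be read as descriptive.

TF/module activity is a one-tailed signed-rank scheme: gene statistics are
converted to normal scores by rank quantile; `NES = Σ mode_i z_i / sqrt(n)`
over a regulon's targets with mode −1 for repressed targets and +1
otherwise (module activity: all +1); p from the standard normal. The null
is analytically N(0,1), confirmed by simulation. Kendall tau-b correlates
module and TF activities over samples where both are FDR-significant
(≥ 8 samples required, otherwise NA with a reason); the two-sample KS test
compares activity distributions between clinically labeled groups.

## Network assembly

Edge costs derive from per-edge citation counts: `s_e = 1/n_sources`
min–max scaled to [0, 1], so the best-documented edge is free and a
single-source edge costs 1 (the alternative reading of the scaling is
available via the cost series directly). Prize nodes are the union of
module-enriched TFs, differentially active TFs (FDR < 0.1) and proteins of
enriched pathways, each at prize 100 tuned by `b × prize − μ × degree`
(floored at 0) with hub penalty μ = 0.005 and degree taken on the full
prior network.

The prize-collecting Steiner forest minimizes `Σ edge costs + w × (number
of trees) + Σ foregone prizes` with per-tree charge w = 40, on the
undirected view of the prior (directions and signs are re-attached to the
output). The solver is a virtual-root heuristic: metric closure over
terminals → MST → expansion to real edges → re-MST with root edges → strong
pruning (bottom-up net worth `nw(v) = prize(v) + Σ max(0, nw(child) −
edge cost)`, root children must beat w). A second candidate prunes the MST
of the whole graph, and the better objective wins; the empty solution is
always considered. When the prior is a forest, an exact dynamic program
(`open/best` recursion with traceback) replaces the heuristic, so tree
instances are solved optimally. On random ≤ 12-node instances the heuristic
stays within 10% of the exhaustive optimum (worst observed ≈ 7%).
Isolated prize nodes absent from the prior survive only if their prize
exceeds w. The randomized variant multiplies each cost by `1 + U(−0.05,
0.05)` per iteration (30 iterations) and unions the solutions.

Supernodes: each module becomes a node with incoming edges from in-network
TFs whose regulons overlap it (Fisher p < 0.1, direction from which signed
test fired), undirected edges to phenotype nodes with `|r| > 0.5 and
p < 0.05`, and weight-1 feedback edges to member proteins present in the
network. Isolated supernodes are dropped with a log entry.

## Propagation

Term information content is `−ln` of the ancestor-propagated annotation
frequency over the annotated gene universe; the Resnik pairwise similarity
is the IC of the most informative common ancestor, and the gene-level
score is the best-match average over the two annotation sets. Protein–
protein edge weights become the min–max-scaled similarity multiplied by the
prior sign (weights in [−1, 1]); supernode and feedback edges stay at 1.

The random walk with restart uses restart probability r = 0.95 and a
row-normalized transition matrix built from `max(weight, 0)` — negative
regulation carries no walk probability by default; an `|weight|` mode is
provided since the upstream tooling's treatment of signed weights is not
documented. Dangling-node mass returns to the seeds, which makes the
stationary distribution proportional to the closed form
`(I − (1−r) Wᵀ)⁻¹ s` renormalized to unit mass; the implementation
iterates to an L1 change below 1e−10 and matches the direct solve to
1e−8. Seed significance reassigns the observed seed masses to uniformly
random node sets (10 000 draws by default, the node itself not excluded)
and uses the `≥`-counting rule with the +1 correction; a consequence of
uniform reseeding at high restart is that significance is only attainable
when the seed count is well below `alpha × network size`, which sets a
floor on useful network sizes. Explanation subgraphs union all shortest
paths (edge distance `1 − |weight|`, floored at 1e−6) from each source TF
to the target.

## Drug influence and flow

Drug profiles keep binding-class-1 targets only and drop drugs with more
than five such targets. Morphology responses become per-cell log10 fold
changes against the pooled batch-control mean (dual-dye spot counts are
averaged first; a zero control mean masks the feature for that batch).
The influence score of a drug with target set K on a network with node set
N is

    S = [Σ_{x ∈ K∩N} PR(x)] × |K∩N| / min(|K|, |N|),

with PageRank computed on the undirected view with |weight| edge weights
and damping 0.85 (damping and weight handling are this package's choices;
only the algorithm itself is prescribed). Validation compares |LFC|
distributions between in-network and out-network drugs (Welch t and KS per
feature) and rank-correlates S with per-drug mean |LFC| (Spearman); the
per-drug aggregate is the mean of per-cell absolute changes.

Max flow runs on the directed network with the unsigned similarity as edge
capacity (capacity 1 on supernode/feedback edges); the reported subnetwork
keeps flow-carrying edges at or above the 99th percentile of positive
flows (linear interpolation, ties included). An undirected mode mirrors
the directed default.

## Synthetic data

The generator plants every structure the pipeline is meant to recover.
Expression uses a latent-factor model: module gene = `sqrt(ρ) × factor +
sqrt(1−ρ) × noise` with within-module correlation ρ = 0.8 by default,
four modules of 50/40/35/30 genes, 200 background genes and 100 samples,
exponentiated to an FPKM-like scale. Shape features are noisy copies of
the module factors at target correlations (0.8, −0.8, 0.7, 0.6; remaining
features are pure noise). Counts are negative binomial (mean 100,
dispersion 0.05, library sizes in [0.7, 1.4]) with the first two modules
planted up/down by one log2 unit, keeping module-planted regulons
consistent with a signed TF activity. The prior network is a
preferential-attachment graph oriented hub→spoke (heavy-tailed out-degree)
over 400 nodes covering the gene universe plus 16 TFs, with 70% activating
edges and truncated-geometric citation counts in 1..25. Half the regulons
(15 targets, 20% unknown sign) are planted inside modules; pathway gene
sets tile the universe with deliberately uneven TF membership (two TF-rich
pathways) so TF→pathway enrichment has recoverable signal. The ontology is
a depth-4, branching-3 tree with sparse cross-links and 1–3 annotations
per gene. The drug screen gives each drug 1–5 class-1 targets alternately
inside and outside the network and draws per-cell morphology values at
`baseline × 10^(slope × influence + noise)` with slope 10 and noise SD
0.05, placing central-target effects near 0.2–0.4 log10 units, in the
range of real kinase-inhibitor screens.

What the synthetic data do **not** emulate: per-gene mean–variance trends
and count overdispersion heterogeneity, batch structure in expression,
correlated shape features, literature bias in the prior (beyond citation
skew), regulon size variation, multi-batch drug screens, and any real gene
identities. Passing tests therefore demonstrate that each algorithm
recovers the structure it is specified to recover under its stated model —
not that the pipeline's biological conclusions transfer to any particular
dataset.

## Problem sizes and determinism

Defaults are chosen so the full pipeline (seven stages, 1000 shape
permutations, 1000 resampled modules, 30 PCSF iterations, 10 000 walk
randomizations) completes in well under a minute on one CPU and is
byte-identical across reruns with the same seed; every stochastic routine
takes an explicit seed derived from the global one, and all outputs are
written with fixed float formatting. Tests that compare against exhaustive
oracles use ≤ 12-node instances where enumeration is exact.

## Known limitations

- The PCSF heuristic carries no approximation guarantee on general graphs;
  the 10% oracle bound is an empirical property at small n.
- Seed-randomization significance is conservative by construction (the +1
  correction and self-seeding) and uninformative on very small networks.
- The NB Wald test is mildly anticonservative at small n and is not a
  substitute for a full GLM analysis when one is available.
- The rank-matched permutation procedure for module–shape correlations is
  anticonservative for null features that share a matrix with strong true
  signals (see above); its p-values are best read jointly with the
  Student p and the |r| threshold.
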