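# Methods

## Model

`infrank` scores the influence of each gene in a two-group (tumor/normal)
expression study by a topic-sensitive PageRank over a condition-specific
weighted network. The premise is that an influential gene (i) is itself
perturbed between the groups and (ii) sits upstream of many interactions
that are actually active in the condition. Three model components encode
this.

**Mixed-edge influence distance.** The background network holds directed
regulatory edges (pathway maps) and undirected binding edges (binary
interactome). A path is admissible when it crosses directed edges forward
only and undirected edges in either orientation; the influence distance
d(u → v) is the minimal admissible path length, computed by breadth-first
search per source. If d(u → v) = d, v is downstream of u at distance d.
A single traversal rule covers both mixed cases (directed-then-undirected
and undirected-then-directed); as a consequence a purely undirected path
also confers an upstream/downstream relation. For users who prefer the
stricter reading, `require_directed=True` (CLI `--require-directed`) runs
the BFS over (node, crossed-a-directed-edge) states and demands at least
one directed edge per path; the worked six-node example is unchanged
either way. Unreachable pairs are simply absent from the distance table.
The default cap of 15 steps reflects the diameter-scale distance observed
on merged pathway + interactome networks of ~8–9k proteins and is
configurable.

**Dynamic network.** For every ordered pair in the distance table with
both genes expressed, the Pearson correlation of the two expression
profiles is computed on log2(x + 1)-transformed values (RSEM-scale data is
heavy-tailed; the transform is configurable off). A pair is retained iff
|PCC| > 0.7 — strict inequality, the conventional co-expression cutoff —
and weighted |PCC|/d. The signed PCC is kept as edge metadata; the random
walk uses the magnitude, since a negative transition weight has no
probabilistic meaning. No correlation p-value is applied on top of the
threshold. Whether PCC pools all samples or uses tumor samples only is
configurable (`pcc_samples`, default "all").

**Ranking.** With M the column-stochastic transition matrix of the dynamic
network (column u distributes mass to its targets proportionally to edge
weight), s the topic vector and β the teleport probability:

    ν(t) = (1 − β) M ν(t−1) + β s/|s|,   ν(0) = 1/N.

The topic weight is |log2 FC| with FC = (mean_tumor + 1)/(mean_normal + 1);
the pseudocount keeps near-zero normal means finite and the magnitude
treats up- and down-regulation symmetrically (raw-ratio FC is available via
`topic fc`). Dangling columns (genes with no retained outgoing edge) are
replaced by the normalized topic vector, consistent with the
topic-sensitive teleport; a uniform alternative is available. The ranking
universe is the set of genes present in both network and expression matrix,
so isolated expressed genes participate through teleport mass only.
Iteration stops when MAIS = max_i |ν_i(t) − ν_i(t−1)| < 1e-5 (cap 1000
iterations; non-convergence is flagged, not raised). Because M is column
stochastic and s/|s| sums to one, Σν(t) = 1 at every step — checked at run
time — and the l1 difference contracts by (1 − β) per iteration, so
convergence is guaranteed; in practice instances converge in well under
30 steps. Ranks break score ties lexicographically for reproducibility.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pcc_threshold` | 0.7 | strict magnitude cutoff for co-expression |
| `beta` | 0.2 | teleport probability of the ranking walk |
| `tol` | 1e-5 | MAIS stopping tolerance |
| `cap` | 15 | maximum influence distance retained |
| `topic_mode` | `abslog2fc` | topic weight; `fc` uses the raw ratio |
| `n_perm` | 1000 | null repetitions for empirical p-values |

## Significance

The null model rewires the dynamic network's directed edges preserving
every node's in- and out-degree (degree is the topological quantity most
confounded with PageRank mass; an Erdős–Rényi null with matched edge count
is available via `model="er"`), shuffles the edge-attribute triples among
edge slots, and reassigns the topic weights to genes uniformly at random.
Each repetition re-runs the full ranking; with n null scores strictly
greater than the observed score, p = (n + 1)/n_perm — the divisor is
n_perm itself, so the smallest attainable p is 1/n_perm. No
multiple-testing correction is applied. One `SeedSequence` is split per
repetition index, making results independent of execution order. The
randomization operates on the already-built dynamic network; the
co-expression filter is not re-applied to the rewired graph.

## Synthetic data

The generator emulates the statistical structure the dynamic-network step
assumes: interacting pairs are strongly co-expressed and a perturbed master
regulator drives its targets. Expression is 2^z − 1 with z Gaussian on the
log2 scale (mean 8, within-group sd 0.5), so the log2(x + 1) transform
recovers z exactly and planted correlations survive the pipeline. Each
planted regulator is shifted by its log2FC in tumor samples and wired by
directed edges to its targets; each target is slope·(regulator − pooled
mean) + Gaussian noise, with the slope calibrated from (target PCC, noise
sd, regulator pooled sd) so the pooled-sample population correlation equals
the requested PCC. Targets thereby inherit a damped fold change
(slope·log2FC ≈ 1.1 under defaults), which keeps the regulator the
dominant topic weight — the property that makes parameter recovery a sharp
test. Decoy background edges are drawn among the independent-noise genes
only, so they feed the distance table with candidate pairs the
co-expression filter must reject without wiring the planted sub-network to
anything else. Defaults: 50 genes, 30 + 30 samples, one regulator with 20
targets at PCC 0.9, |log2FC| = 2, noise sd 0.3.

What the generator does **not** emulate: RNA-seq count overdispersion
(negative binomial), batch effects, correlated noise between unrelated
genes, or hub-dominated degree distributions. Passing the recovery test
therefore shows the pipeline's machinery is correct and sensitive under
its own assumptions, not that it will rank true drivers first on real
tumor data, where signal is weaker and confounded.

## Numerical and design choices

- BFS distances are integers; no tie-breaking is needed.
- Genes missing in more than 10% of samples are removed at load; the
  residual missing entries of retained genes are set to 0 (not detected).
- Zero-variance expression profiles cannot be correlated; such pairs are
  skipped with a log entry rather than raising.
- The subsample-stability diagnostic resamples stratified within the tumor
  and normal groups at the given fraction, keeping both groups non-empty
  at any fraction.
- The differential-expression comparison list is a plain |log2 FC| top-m
  ranking.
- Community detection on the seed-gene sub-network is out of scope; the
  module emits the distance-annotated edge list and leaves module calling
  to the user. Survival and clinical-covariate analyses are likewise out
  of scope.
- Problem sizes in the test suite (graphs of ≤ 20 nodes for oracle
  equivalence, 100-seed recovery runs on 50-gene datasets, 200-repetition
  permutation checks) were chosen so each check isolates one property at
  desk scale.

## Known limitations

- Edge signs (activation vs inhibition) are not modeled; all pathway
  relation subtypes import as unsigned directed edges.
- Gene identifiers are plain strings; only a user-supplied two-column
  alias table is honored, no identifier service.
- The degree-preserving rewiring uses attempted double-edge swaps (10
  attempts per edge by default); for very dense graphs the null may mix
  slowly.
- PCC is the only co-expression measure; rank-based or information-
  theoretic alternatives are not provided.
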