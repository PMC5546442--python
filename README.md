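# infrank

Ranking the influence of genes in a condition-specific biological network.

High-throughput expression experiments routinely return hundreds of
differentially expressed genes; the hard part is deciding which of them
*drive* the condition. `infrank` implements an influence-ranking pipeline
for that question, aimed at computational biologists working with paired
tumor/normal (or any two-group) RNA-seq data and curated interaction
networks:

1. **Background network.** Directed regulatory edges from pathway maps
   (KGML XML) are merged with undirected binding edges from binary
   protein-interaction screens into one mixed graph.
2. **Influence distance.** d(u → v) is the minimal number of consecutive
   steps from u to v, crossing directed edges forward only and undirected
   edges either way; v is then *downstream* of u at distance d.
3. **Dynamic network.** A gene pair at distance d is kept only when the
   Pearson correlation of its expression satisfies |PCC| > 0.7, and the
   retained edge is weighted PCC/d — interactions must be active in the
   condition, and influence decays with distance.
4. **Topic-sensitive PageRank.** Influence scores ν follow

       ν(t) = (1 − β) M ν(t−1) + β s/|s|,   ν(0) = 1/N

   where M is the column-stochastic transition matrix of the dynamic
   network, s is the per-gene |log2 fold change| topic vector, and β = 0.2.
   Iteration stops when the maximum absolute score change (MAIS) drops
   below 1e-5. A gene scores highly when it is strongly perturbed *and*
   feeds many active downstream interactions.
5. **Significance.** Empirical p-values p = (n + 1)/n_perm from
   degree-preserving network rewiring plus random reassignment of fold
   changes, re-ranking each of n_perm (default 1000) null instances.

Diagnostics cover distance-cutoff convergence of the ranking (IR₁…IR_k),
top-k stability under sample subsampling, k-core and plain-PageRank
baselines, and seed-gene sub-network extraction.

## Worked example

No external downloads are needed: the `synthetic` module generates seeded
datasets with a planted master regulator (by default 50 genes, 30 tumor +
30 normal samples, one regulator driving 20 targets at PCC 0.9 with
|log2FC| = 2).

```python
import infrank as ir
from infrank.dynamic import build_dynamic_network
from infrank.tspr import build_transition, fold_change, tspr_run

net, expr, truth = ir.generate(ir.SyntheticSpec(seed=7))
dist = ir.all_pairs(net, cap=15)
dyn = build_dynamic_network(net, dist, expr)
res = tspr_run(build_transition(dyn), fold_change(expr))
print(res.iterations, res.converged)
for g in res.top(5):
    print(g, round(res.scores[g], 4), res.ranks[g])
```

prints

```
4 True
REG1 0.0658 1
G003 0.046 2
G018 0.0422 3
G015 0.0415 4
G016 0.041 5
```

The planted regulator `REG1` is ranked first: it carries the largest
teleport weight (|log2FC| ≈ 2 versus ≈ 1.1 for its targets) and is the only
gene with retained outgoing edges, so both terms of the update favour it.
The remaining genes receive teleport mass roughly in proportion to their
fold changes. The same pipeline is available from the shell:

```bash
infrank synth --seed 7 --out-dir fixtures/
infrank run --config run.yaml        # or stage by stage:
infrank build-network --kgml fixtures/ --ppi fixtures/ppi.tsv --out net.tsv
infrank distances --net net.tsv --cap 15 --out dist.tsv
infrank dynamic --net net.tsv --dist dist.tsv --expr fixtures/expression.tsv \
    --groups fixtures/groups.tsv --out dyn.tsv
infrank rank --dyn dyn.tsv --expr fixtures/expression.tsv \
    --groups fixtures/groups.tsv --out scores.tsv
```

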