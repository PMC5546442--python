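"""Diagnostics and baseline comparisons for influence rankings.

Covers the distance-cutoff convergence study (IR_1 ... IR_k), subsample
stability of the top-k list, k-core and plain-PageRank baselines, the
pairwise distance profile of a gene set, and seed-gene sub-network
extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .distance import DistanceTable
from .dynamic import ExpressionMatrix, build_dynamic_network
from .tspr import TSPRConfig, build_transition, fold_change, tspr_run, uniform_topic

__all__ = [
    "ConvergenceReport",
    "StabilityReport",
    "rank_by_cutoff",
    "subsample_stability",
    "kcore_baseline",
    "pagerank_baseline",
    "top_fold_change",
    "pairwise_distance_profile",
    "seed_subnetwork",
]


@dataclass
class ConvergenceReport:
    """Spearman agreement of IR_k rankings with the final cutoff's ranking.

    ``spearman[k]`` is rho between the ranks of the final cutoff's top-m
    genes under IR_k and under IR_{k_max}; None when the cutoff-k network is
    empty.
    """

    cutoffs: list
    rank_lists: dict  # cutoff -> {gene: rank} over the top-m genes
    spearman: dict  # cutoff -> rho or None
    top_genes: list


@dataclass
class StabilityReport:
    n_resamples: int
    subsample_size: int
    k: int
    overlaps: list
    mean: float
    sd: float
    full_top: list = field(default_factory=list)


def rank_by_cutoff(net, dist: DistanceTable, expr: ExpressionMatrix,
                   cfg: TSPRConfig = TSPRConfig(), k_max: int = 15,
                   m: int = 100, pcc_threshold: float = 0.7) -> ConvergenceReport:
    """Influence rankings under increasing distance cutoffs.

    IR_k uses only gene pairs at influence distance <= k. The report
    compares each IR_k with IR_{k_max} by Spearman rho over the top-m genes
    of the final ranking; a rapidly saturating rho means long-range pairs
    barely move the ranking.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    dyn_full = build_dynamic_network(net, dist, expr, pcc_threshold=pcc_threshold)
    topic = fold_change(expr)
    universe = sorted(dyn_full.node_universe)
    results = {}
    for k in range(1, k_max + 1):
        dyn_k = dyn_full.restrict_distance(k)
        if not dyn_k.edges:
            results[k] = None
            continue
        results[k] = tspr_run(build_transition(dyn_k, universe), topic, cfg)
    final = results[k_max]
    if final is None:
        raise ValueError("final cutoff produced an empty dynamic network")
    top = final.top(m)
    rank_lists = {}
    spearman = {}
    for k, res in results.items():
        if res is None:
            rank_lists[k] = None
            spearman[k] = None
            continue
        rank_lists[k] = {g: res.ranks[g] for g in top}
        rho = stats.spearmanr([res.ranks[g] for g in top],
                              [final.ranks[g] for g in top]).statistic
        spearman[k] = float(rho)
    return ConvergenceReport(cutoffs=list(range(1, k_max + 1)),
                             rank_lists=rank_lists, spearman=spearman,
                             top_genes=top)


def subsample_stability(net, dist: DistanceTable, expr: ExpressionMatrix,
                        cfg: TSPRConfig = TSPRConfig(), k: int = 20,
                        n_resamples: int = 100, fraction: float = 0.5,
                        seed: int = 0,
                        pcc_threshold: float = 0.7) -> StabilityReport:
    """Overlap of the top-k list between subsampled and full-data runs.

    Each resample draws ``fraction`` of the samples without replacement,
    stratified within the tumor and normal groups so both stay non-empty,
    rebuilds the dynamic network and topic vector, reruns the ranker, and
    records |top-k ∩ full-data top-k|.
    """
    tumor = expr.samples_in_group("tumor")
    normal = expr.samples_in_group("normal")
    n_t = int(round(fraction * len(tumor)))
    n_n = int(round(fraction * len(normal)))
    if n_t < 2 or n_n < 2:
        raise ValueError("fraction too small: each group needs >= 2 samples")
    dyn_full = build_dynamic_network(net, dist, expr, pcc_threshold=pcc_threshold)
    universe = sorted(dyn_full.node_universe)
    full = tspr_run(build_transition(dyn_full, universe), fold_change(expr), cfg)
    full_top = set(full.top(k))
    overlaps = []
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    for rep in range(n_resamples):
        rng = np.random.default_rng(children[rep])
        keep = sorted(rng.choice(tumor, size=n_t, replace=False)) + \
            sorted(rng.choice(normal, size=n_n, replace=False))
        sub = expr.subset_samples(keep)
        dyn = build_dynamic_network(net, dist, sub, pcc_threshold=pcc_threshold)
        if not dyn.edges:
            overlaps.append(0)
            continue
        res = tspr_run(build_transition(dyn, universe), fold_change(sub), cfg)
        overlaps.append(len(set(res.top(k)) & full_top))
    arr = np.array(overlaps, dtype=float)
    return StabilityReport(n_resamples=n_resamples, subsample_size=n_t + n_n,
                           k=k, overlaps=overlaps, mean=float(arr.mean()),
                           sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                           full_top=sorted(full_top))


def _undirected_view(net) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.directed_edges)
    g.add_edges_from(net.undirected_edges)
    return g


def kcore_baseline(net, de_genes, k_top: int) -> list:
    """Differentially expressed genes ranked by coreness.

    Coreness on the undirected view of the background network; ties broken
    by degree, then gene id.
    """
    g = _undirected_view(net)
    core = nx.core_number(g)
    pool = [x for x in de_genes if x in core]
    pool.sort(key=lambda x: (-core[x], -g.degree(x), x))
    return pool[:k_top]


def pagerank_baseline(net, k_top: int, beta: float = 0.2,
                      tol: float = 1e-5) -> list:
    """Plain PageRank on the unweighted background network.

    Uniform teleport at probability ``beta``; undirected edges walkable in
    both orientations. Implemented with the same power-iteration engine as
    the influence ranker, with a uniform topic vector.
    """
    from .dynamic import DynamicNetwork, DynEdge

    edges = {}
    for u, v in net.directed_edges:
        edges[(u, v)] = DynEdge(pcc=1.0, distance=1, weight=1.0)
    for a, b in net.undirected_edges:
        edges.setdefault((a, b), DynEdge(pcc=1.0, distance=1, weight=1.0))
        edges.setdefault((b, a), DynEdge(pcc=1.0, distance=1, weight=1.0))
    dyn = DynamicNetwork(edges=edges, node_universe=set(net.nodes))
    cfg = TSPRConfig(beta=beta, tol=tol, dangling="uniform")
    res = tspr_run(build_transition(dyn, sorted(net.nodes)),
                   uniform_topic(net.nodes), cfg)
    return res.top(k_top)


def top_fold_change(expr: ExpressionMatrix, k_top: int) -> list:
    """Top genes by |log2 fold change| — the plain differential-expression
    stand-in used in distance-profile comparisons."""
    topic = fold_change(expr)
    order = sorted(topic.weights, key=lambda g: (-topic.weights[g], g))
    return order[:k_top]


def pairwise_distance_profile(gene_set, dist: DistanceTable):
    """Distance histogram among ordered pairs of a gene set.

    Returns (histogram distance -> pair count, list of isolated genes). A
    gene is isolated when it is unreachable from and to every other member.
    """
    genes = list(gene_set)
    hist: dict = {}
    connected = set()
    for u in genes:
        for v in genes:
            if u == v:
                continue
            d = dist.get(u, v)
            if d is not None:
                hist[d] = hist.get(d, 0) + 1
                connected.add(u)
                connected.add(v)
    isolated = [g for g in genes if g not in connected]
    return hist, isolated


def seed_subnetwork(seeds, dist: DistanceTable, max_d: int = 3) -> list:
    """Activated sub-network among seed genes.

    All ordered seed pairs at influence distance <= max_d, each annotated
    with its distance class (1 = direct interaction).
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    seeds = list(seeds)
    out = []
    for u in seeds:
        for v in seeds:
            if u == v:
                continue
            d = dist.get(u, v)
            if d is not None and d <= max_d:
                out.append((u, v, d))
    return out


def spearman_rho(ranks_a, ranks_b) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    if len(ranks_a) != len(ranks_b):
        raise ValueError("length mismatch")
    rho = stats.spearmanr(ranks_a, ranks_b).statistic
    return float(rho) if not math.isnan(rho) else math.nan
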