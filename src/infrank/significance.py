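"""Permutation significance of influence scores.

The null model randomizes both the wiring and the topic: the dynamic
network's directed edges are rewired preserving every node's in- and
out-degree (edge weights are shuffled among edge slots), and the fold-change
values are reassigned to genes uniformly at random. Re-running the ranker on
each randomized instance yields a per-gene null score distribution; with n
null scores strictly greater than the observed score over n_perm
repetitions, the empirical p-value is (n + 1) / n_perm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamic import DynamicNetwork, DynEdge
from .tspr import TSPRConfig, TopicVector, build_transition, tspr_run

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "randomize_network",
    "permute_topic",
    "pvalue_from_count",
    "empirical_pvalues",
]


@dataclass
class PermutationResult:
    pvalues: dict
    n_perm: int
    null_exceed_counts: dict
    seed: int
    observed: dict = field(default_factory=dict)


def pvalue_from_count(n: int, n_perm: int) -> float:
    """p = (n + 1) / n_perm with n null scores above the observed one.

    The divisor is n_perm itself (1000 in the original procedure), so the
    smallest attainable p is 1/n_perm and n = n_perm - 1 gives exactly 1.
    """
    if not 0 <= n < n_perm:
        raise ValueError("need 0 <= n < n_perm")
    return (n + 1) / n_perm


def _rewire_directed(edges: list, rng: np.random.Generator,
                     n_attempts: int) -> list:
    """Degree-preserving double-edge swaps on a directed edge list."""
    edges = list(edges)
    present = set(edges)
    m = len(edges)
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # swap targets: (a,b),(c,d) -> (a,d),(c,b)
        if a == c or b == d or a == d or c == b:
            continue
        if (a, d) in present or (c, b) in present:
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add((a, d))
        present.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    return edges


def randomize_network(dyn: DynamicNetwork, seed, model: str = "degree",
                      swap_factor: int = 10) -> DynamicNetwork:
    """Seeded randomization of the dynamic network.

    ``model="degree"`` (default) rewires directed edges preserving in- and
    out-degree sequences; ``model="er"`` draws the same number of edges
    uniformly among ordered non-loop pairs. In both cases the multiset of
    edge attribute triples (pcc, distance, weight) is shuffled among the
    edge slots. Networks with fewer than 2 edges are returned unchanged.
    """
    rng = np.random.default_rng(seed)
    pairs = sorted(dyn.edges)
    if len(pairs) < 2:
        logger.warning("network too small to rewire (%d edge(s)); unchanged",
                       len(pairs))
        return DynamicNetwork(edges=dict(dyn.edges),
                              node_universe=set(dyn.node_universe))
    attrs = [dyn.edges[p] for p in pairs]
    if model == "degree":
        new_pairs = _rewire_directed(pairs, rng, swap_factor * len(pairs))
    elif model == "er":
        nodes = sorted(dyn.nodes)
        candidates = [(u, v) for u in nodes for v in nodes if u != v]
        take = rng.choice(len(candidates), size=len(pairs), replace=False)
        new_pairs = [candidates[i] for i in take]
    else:
        raise ValueError(f"unknown randomization model {model!r}")
    perm = rng.permutation(len(attrs))
    edges = {p: attrs[k] for p, k in zip(new_pairs, perm)}
    return DynamicNetwork(edges=edges, node_universe=set(dyn.node_universe))


def permute_topic(topic: TopicVector, seed) -> TopicVector:
    """Uniformly random reassignment of the topic weights to genes."""
    rng = np.random.default_rng(seed)
    genes = sorted(topic.weights)
    vals = np.array([topic.weights[g] for g in genes], dtype=float)
    return TopicVector(weights=dict(zip(genes, vals[rng.permutation(len(vals))])))


def empirical_pvalues(dyn: DynamicNetwork, topic: TopicVector,
                      cfg: TSPRConfig = TSPRConfig(), n_perm: int = 1000,
                      seed: int = 0, model: str = "degree") -> PermutationResult:
    """Per-gene empirical p-values from n_perm randomized re-rankings.

    One SeedSequence is split per repetition index, so results do not depend
    on execution order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = sorted(dyn.node_universe)
    observed = tspr_run(build_transition(dyn, universe), topic, cfg).scores
    counts = {g: 0 for g in universe}
    children = np.random.SeedSequence(seed).spawn(n_perm)
    for rep in range(n_perm):
        net_ss, topic_ss = children[rep].spawn(2)
        null_dyn = randomize_network(dyn, net_ss, model=model)
        null_topic = permute_topic(topic, topic_ss)
        null = tspr_run(build_transition(null_dyn, universe), null_topic, cfg)
        for g in universe:
            if null.scores[g] > observed[g]:
                counts[g] += 1
    pvalues = {g: pvalue_from_count(c, n_perm) for g, c in counts.items()}
    return PermutationResult(pvalues=pvalues, n_perm=n_perm,
                             null_exceed_counts=counts, seed=seed,
                             observed=observed)
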