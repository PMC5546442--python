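"""Topic-sensitive PageRank over the dynamic network.

The influence score v obeys the fixed-point iteration

    v(t) = (1 - beta) * M v(t-1) + beta * s / |s|,     v(0) = 1/N

where M is the column-stochastic transition matrix of the weighted dynamic
network, s is the topic vector derived from expression fold change, |s| its
sum, and beta the teleport probability (0.2 by convention). Iteration stops
when the maximum absolute score change between steps (MAIS) falls below the
tolerance (1e-5). Genes both perturbed (high |log2 FC|) and feeding many
active downstream interactions accumulate score: these are the influential
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dynamic import DynamicNetwork, ExpressionMatrix

__all__ = [
    "TSPRConfig",
    "TopicVector",
    "TransitionModel",
    "TSPRResult",
    "fold_change",
    "uniform_topic",
    "build_transition",
    "tspr_run",
    "mais",
    "rank_genes",
]


@dataclass(frozen=True)
class TSPRConfig:
    beta: float = 0.2
    tol: float = 1e-5
    max_iter: int = 1000
    dangling: str = "topic"  # "topic" | "uniform"

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.dangling not in ("topic", "uniform"):
            raise ValueError("dangling must be 'topic' or 'uniform'")


@dataclass
class TopicVector:
    """Non-negative per-gene teleport weights (fold-change derived)."""

    weights: dict = field(default_factory=dict)

    @property
    def norm(self) -> float:
        return float(sum(self.weights.values()))

    def get(self, gene) -> float:
        return self.weights.get(gene, 0.0)


def fold_change(expr: ExpressionMatrix, pseudocount: float = 1.0,
                mode: str = "abslog2fc") -> TopicVector:
    """Topic vector from tumor/normal fold change.

    FC = (mean tumor + pseudocount) / (mean normal + pseudocount) on the raw
    expression scale. The default topic weight is |log2 FC|, treating up-
    and down-regulation symmetrically; ``mode="fc"`` uses the raw ratio.
    """
    tumor = expr.samples_in_group("tumor")
    normal = expr.samples_in_group("normal")
    if not tumor or not normal:
        raise ValueError("both tumor and normal groups must be non-empty")
    mt = expr.data[tumor].mean(axis=1) + pseudocount
    mn = expr.data[normal].mean(axis=1) + pseudocount
    fc = mt / mn
    if mode == "abslog2fc":
        w = np.abs(np.log2(fc))
    elif mode == "fc":
        w = fc
    else:
        raise ValueError(f"unknown topic mode {mode!r}")
    return TopicVector(weights=dict(zip(expr.genes, w.astype(float))))


def uniform_topic(genes) -> TopicVector:
    """Uniform teleport vector; turns the engine into plain PageRank."""
    return TopicVector(weights={g: 1.0 for g in genes})


@dataclass
class TransitionModel:
    """Column-stochastic transition matrix over an ordered node universe.

    ``matrix`` has M[i, j] = P(step j -> i) for non-dangling columns;
    dangling columns (nodes with no outgoing weight) are all-zero here and
    replaced at iteration time by the teleport distribution, after which
    every column sums to 1.
    """

    nodes: list
    matrix: sp.csr_matrix
    dangling: np.ndarray  # boolean mask over nodes

    @property
    def n(self) -> int:
        return len(self.nodes)

    def dense_with_dangling(self, d_vec: np.ndarray) -> np.ndarray:
        """Dense column-stochastic matrix with dangling columns = d_vec."""
        m = self.matrix.toarray()
        m[:, self.dangling] = d_vec[:, None]
        return m


def build_transition(dyn: DynamicNetwork, universe=None) -> TransitionModel:
    """Column-normalize the dynamic network's edge weights.

    ``universe`` defaults to the dynamic network's node universe (genes in
    both the background network and the expression matrix), so isolated
    expressed genes participate via teleport mass only.
    """
    nodes = sorted(universe if universe is not None else dyn.node_universe)
    if not nodes:
        raise ValueError("empty node universe")
    index = {g: i for i, g in enumerate(nodes)}
    out = dyn.out_weights()
    rows, cols, vals = [], [], []
    dangling = np.ones(len(nodes), dtype=bool)
    for u, targets in out.items():
        if u not in index:
            continue
        kept = {v: w for v, w in targets.items() if v in index}
        total = sum(kept.values())
        if total <= 0:
            continue
        dangling[index[u]] = False
        for v, w in kept.items():
            rows.append(index[v])
            cols.append(index[u])
            vals.append(w / total)
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return TransitionModel(nodes=nodes, matrix=matrix, dangling=dangling)


def mais(v_new, v_old) -> float:
    """Maximum absolute per-gene score change between iterations."""
    v_new = np.asarray(v_new, dtype=float)
    v_old = np.asarray(v_old, dtype=float)
    if v_new.shape != v_old.shape:
        raise ValueError("length mismatch")
    return float(np.max(np.abs(v_new - v_old)))


def rank_genes(scores: dict) -> dict:
    """Ranks 1..N, descending score, ties broken lexicographically."""
    order = sorted(scores, key=lambda g: (-scores[g], g))
    return {g: i + 1 for i, g in enumerate(order)}


@dataclass
class TSPRResult:
    scores: dict
    ranks: dict
    iterations: int
    mais_trace: list
    converged: bool

    def top(self, k: int) -> list:
        order = sorted(self.ranks, key=self.ranks.get)
        return order[:k]


def tspr_run(model: TransitionModel, topic: TopicVector,
             cfg: TSPRConfig = TSPRConfig()) -> TSPRResult:
    """Power-iterate the topic-sensitive PageRank to the MAIS criterion.

    Scores sum to 1 at every step (checked); non-convergence within
    ``max_iter`` is reported via ``converged=False``, not raised.
    """
    n = model.n
    s = np.array([topic.get(g) for g in model.nodes], dtype=float)
    if np.any(s < 0):
        raise ValueError("topic weights must be non-negative")
    s_norm = s.sum()
    if s_norm <= 0:
        raise ValueError("topic vector is all zero on the node universe")
    tele = s / s_norm
    d_vec = tele if cfg.dangling == "topic" else np.full(n, 1.0 / n)

    v = np.full(n, 1.0 / n)
    trace: list = []
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        dangling_mass = float(v[model.dangling].sum())
        v_new = (1.0 - cfg.beta) * (model.matrix @ v + dangling_mass * d_vec) \
            + cfg.beta * tele
        total = float(v_new.sum())
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"score conservation violated: sum={total!r}")
        delta = mais(v_new, v)
        trace.append(delta)
        v = v_new
        if delta < cfg.tol:
            converged = True
            break
    scores = dict(zip(model.nodes, v))
    return TSPRResult(scores=scores, ranks=rank_genes(scores),
                      iterations=iterations, mais_trace=trace,
                      converged=converged)
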