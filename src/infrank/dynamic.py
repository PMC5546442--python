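"""Context-specific dynamic network: co-expression filtering + weighting.

The static background network lists every curated interaction; only a small
fraction is active in a given condition. Gene pairs at influence distance d
are retained when the magnitude of the Pearson correlation of their
expression profiles exceeds a threshold (default 0.7, strict), and each
retained edge is weighted by PCC / d so that influence decays with network
distance. The signed PCC is kept as edge metadata; the transition model uses
the magnitude (a negative transition weight has no meaning in a random
walk).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DynamicNetwork",
    "load_expression",
    "pcc",
    "build_dynamic_network",
    "coexpression_profile",
    "write_dynamic_network",
    "read_dynamic_network",
]

MISSING_FRACTION = 0.10  # genes absent in more than 10% of samples are dropped


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative normalized expression (RSEM scale).

    ``groups`` labels each sample "tumor" or "normal"; labels are required
    only when a fold change is requested.
    """

    data: pd.DataFrame  # genes x samples
    groups: dict = field(default_factory=dict)

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    def samples_in_group(self, label: str) -> list:
        return [s for s in self.samples if self.groups.get(s) == label]

    def log2_values(self) -> pd.DataFrame:
        """log2(x + 1) transform; the scale on which PCC is computed."""
        return np.log2(self.data + 1.0)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            data=self.data[samples],
            groups={s: self.groups[s] for s in samples if s in self.groups},
        )


def load_expression(path, groups_path=None) -> ExpressionMatrix:
    """Load an expression TSV (first column gene id) and a group TSV.

    Genes missing (empty/NA) in more than 10% of samples are removed;
    residual missing entries of retained genes are set to 0 (not detected).
    """
    data = pd.read_csv(path, sep="\t", index_col=0)
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to compute correlations")
    frac_missing = data.isna().mean(axis=1)
    drop = frac_missing > MISSING_FRACTION
    if drop.any():
        logger.info("dropping %d gene(s) missing in >%.0f%% of samples",
                    int(drop.sum()), MISSING_FRACTION * 100)
        data = data.loc[~drop]
    n_resid = int(data.isna().sum().sum())
    if n_resid:
        logger.info("filling %d residual missing value(s) with 0", n_resid)
        data = data.fillna(0.0)
    groups: dict = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", header=None,
                          names=["sample", "label"], comment="#")
        unknown = set(gdf["sample"]) - set(data.columns)
        if unknown:
            raise ValueError(f"samples in group file absent from matrix: {sorted(unknown)}")
        groups = dict(zip(gdf["sample"], gdf["label"]))
    return ExpressionMatrix(data=data, groups=groups)


def pcc(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("PCC needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroDivisionError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class DynEdge:
    pcc: float
    distance: int
    weight: float  # |pcc| / distance


@dataclass
class DynamicNetwork:
    """Weighted directed graph of co-expressed upstream->downstream pairs."""

    edges: dict = field(default_factory=dict)  # (u, v) -> DynEdge
    node_universe: set = field(default_factory=set)

    @property
    def nodes(self) -> set:
        out = set()
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return out

    def restrict_distance(self, k: int) -> "DynamicNetwork":
        """Sub-network keeping edges at influence distance <= k (IR_k)."""
        return DynamicNetwork(
            edges={p: e for p, e in self.edges.items() if e.distance <= k},
            node_universe=set(self.node_universe),
        )

    def out_weights(self) -> dict:
        out: dict = {}
        for (u, v), e in self.edges.items():
            out.setdefault(u, {})[v] = e.weight
        return out


def build_dynamic_network(
    net,
    dist: DistanceTable,
    expr: ExpressionMatrix,
    pcc_threshold: float = 0.7,
    log_transform: bool = True,
    pcc_samples: str = "all",
) -> DynamicNetwork:
    """Retain distance-table pairs with |PCC| > threshold; weight = |PCC|/d.

    Parameters
    ----------
    pcc_threshold
        Strict magnitude cutoff in (0, 1); the conventional 0.7 by default.
    log_transform
        Compute PCC on log2(x+1)-transformed values (default; expression on
        the RSEM scale is heavy-tailed).
    pcc_samples
        "all" pools every sample; "tumor" uses tumor samples only.
    """
    if not 0 < pcc_threshold < 1:
        raise ValueError("pcc_threshold must be in (0, 1)")
    universe = set(net.nodes) & set(expr.genes)
    if not universe:
        raise ValueError("no genes shared between network and expression matrix")
    if pcc_samples == "tumor":
        cols = expr.samples_in_group("tumor")
        if len(cols) < 3:
            raise ValueError("fewer than 3 tumor samples")
        expr = expr.subset_samples(cols)
    values = expr.log2_values() if log_transform else expr.data

    involved = sorted({g for p in dist.entries for g in p if g in universe})
    idx = {g: i for i, g in enumerate(involved)}
    mat = values.loc[involved].to_numpy(dtype=float)
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat) if len(involved) > 1 else np.ones((1, 1))

    n_zero_var = 0
    edges: dict = {}
    for (u, v), d in dist.entries.items():
        if u not in idx or v not in idx:
            continue
        if sd[idx[u]] == 0 or sd[idx[v]] == 0:
            n_zero_var += 1
            continue
        r = float(corr[idx[u], idx[v]])
        if abs(r) > pcc_threshold:
            edges[(u, v)] = DynEdge(pcc=r, distance=d, weight=abs(r) / d)
    if n_zero_var:
        logger.info("skipped %d pair(s) with a zero-variance profile", n_zero_var)
    return DynamicNetwork(edges=edges, node_universe=universe)


def coexpression_profile(dyn: DynamicNetwork, dist: DistanceTable) -> pd.DataFrame:
    """Per-distance retained/total pair counts and their ratio.

    Reproduces the diagnostic showing how small a fraction of candidate
    pairs is actually co-expressed at each network distance.
    """
    total: dict = {}
    for (u, v), d in dist.entries.items():
        if u in dyn.node_universe and v in dyn.node_universe:
            total[d] = total.get(d, 0) + 1
    retained: dict = {}
    for e in dyn.edges.values():
        retained[e.distance] = retained.get(e.distance, 0) + 1
    rows = []
    for d in sorted(total):
        t = total[d]
        r = retained.get(d, 0)
        rows.append({"distance": d, "retained": r, "total": t,
                     "ratio": r / t if t else math.nan})
    return pd.DataFrame(rows).set_index("distance")


def write_dynamic_network(dyn: DynamicNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tdistance\tpcc\tweight\n")
        for (u, v), e in sorted(dyn.edges.items()):
            fh.write(f"{u}\t{v}\t{e.distance}\t{e.pcc:.10g}\t{e.weight:.10g}\n")


def read_dynamic_network(path, node_universe=None) -> DynamicNetwork:
    edges: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            u, v, d, r, w = line.split("\t")
            edges[(u, v)] = DynEdge(pcc=float(r), distance=int(d), weight=float(w))
    universe = set(node_universe) if node_universe is not None else \
        {g for p in edges for g in p}
    return DynamicNetwork(edges=edges, node_universe=universe)
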