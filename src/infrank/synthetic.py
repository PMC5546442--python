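"""Seeded synthetic networks and expression matrices with planted structure.

The generator emulates the statistical assumptions the dynamic-network step
relies on: truly interacting gene pairs are strongly co-expressed, and a
perturbed master regulator both shifts its own expression between groups and
drives its targets. Expression values are log-normal-like (2**z - 1 with z
Gaussian on the log2 scale), so the dynamic module's log2(x+1) transform
recovers z exactly and planted correlations carry through to the computed
PCCs.

For each planted regulator R with parameters (n_targets, target_pcc,
log2fc):

* R's log2 expression is mu + log2fc in tumor samples and mu in normals,
  plus within-group Gaussian noise (sd 0.5);
* each target is slope * (R - pooled mean) + noise, with the slope
  calibrated so the pooled-sample population PCC equals target_pcc; the
  target thereby inherits a damped fold change slope * log2fc, keeping the
  regulator the dominant topic weight;
* all remaining genes are independent Gaussian noise with equal group
  means (fold change ~ 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .dynamic import ExpressionMatrix
from .network_io import BackgroundNetwork

__all__ = [
    "SyntheticSpec",
    "generate",
    "figure_toy_network",
    "write_fixture_kgml",
    "write_expression",
    "write_groups",
]

MU = 8.0  # baseline log2 expression
GENE_SD = 0.5  # within-group sd of regulator and noise genes


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; generation is deterministic
    given ``seed``."""

    n_genes: int = 50
    n_tumor: int = 30
    n_normal: int = 30
    n_pathway_edges: int = 30
    n_ppi_edges: int = 30
    planted_regulators: tuple = (("REG1", 20, 0.9, 2.0),)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal) < 1:
            raise ValueError("all counts must be positive")
        for name, n_targets, rho, _ in self.planted_regulators:
            if not 0.7 < rho <= 1.0:
                raise ValueError(f"{name}: target_pcc must be in (0.7, 1]")
            if n_targets < 1:
                raise ValueError(f"{name}: n_targets must be >= 1")


def _calibrate_slope(rho: float, noise_sd: float, sigma_pooled: float) -> float:
    """Slope making the pooled-sample population PCC equal rho.

    corr = slope*sigma / sqrt(slope^2 sigma^2 + noise_sd^2) = rho
    =>   slope = noise_sd * rho / (sigma * sqrt(1 - rho^2)).
    """
    if rho >= 1.0:
        if noise_sd > 0:
            raise ValueError(
                "target_pcc = 1 requires noise_sd = 0 (feasible bound: 0)")
        return 1.0
    if noise_sd == 0:
        return 1.0  # any slope gives PCC exactly 1
    return noise_sd * rho / (sigma_pooled * math.sqrt(1.0 - rho * rho))


def generate(spec: SyntheticSpec):
    """Build (BackgroundNetwork, ExpressionMatrix, ground_truth).

    ground_truth records the planted regulators, their targets and the
    calibrated slopes.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_tumor + spec.n_normal
    samples = [f"T{i + 1:03d}" for i in range(spec.n_tumor)] + \
        [f"N{i + 1:03d}" for i in range(spec.n_normal)]
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    is_tumor = np.array([groups[s] == "tumor" for s in samples])
    p_tumor = spec.n_tumor / n_samples

    reg_names = [r[0] for r in spec.planted_regulators]
    n_targets_total = sum(r[1] for r in spec.planted_regulators)
    n_filler = spec.n_genes - len(reg_names)
    if n_targets_total > n_filler:
        raise ValueError("not enough genes to host all planted targets")
    fillers = [f"G{i + 1:03d}" for i in range(n_filler)]
    genes = reg_names + fillers

    z = np.empty((spec.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    net = BackgroundNetwork()
    net.nodes.update(genes)
    truth = {"regulators": list(reg_names), "targets": {}, "slopes": {}}

    next_target = 0
    for name, n_targets, rho, log2fc in spec.planted_regulators:
        z_reg = MU + log2fc * is_tumor + rng.normal(0.0, GENE_SD, n_samples)
        z[gene_index[name]] = z_reg
        sigma_pooled = math.sqrt(GENE_SD ** 2 +
                                 p_tumor * (1 - p_tumor) * log2fc ** 2)
        slope = _calibrate_slope(rho, spec.noise_sd, sigma_pooled)
        center = MU + p_tumor * log2fc
        targets = fillers[next_target:next_target + n_targets]
        next_target += n_targets
        for t in targets:
            z[gene_index[t]] = MU + slope * (z_reg - center) + \
                rng.normal(0.0, spec.noise_sd, n_samples)
            net.add_directed(name, t, source="pathway")
        truth["targets"][name] = list(targets)
        truth["slopes"][name] = slope
    for g in fillers[next_target:]:
        z[gene_index[g]] = MU + rng.normal(0.0, GENE_SD, n_samples)

    # Decoy edges live among the independent-noise genes only: they feed the
    # distance table with candidate pairs that the co-expression filter must
    # reject, without wiring the planted sub-network to anything else.
    noise_genes = fillers[next_target:]

    def random_pairs(k):
        pairs = []
        guard = 0
        while len(pairs) < k and guard < 50 * k + 100:
            guard += 1
            u, v = rng.choice(len(noise_genes), size=2, replace=False)
            pairs.append((noise_genes[u], noise_genes[v]))
        return pairs

    if len(noise_genes) >= 2:
        for u, v in random_pairs(spec.n_pathway_edges):
            net.add_directed(u, v, source="pathway")
        for u, v in random_pairs(spec.n_ppi_edges):
            net.add_undirected(u, v, source="ppi")

    data = pd.DataFrame(np.power(2.0, z) - 1.0, index=genes, columns=samples)
    expr = ExpressionMatrix(data=data, groups=groups)
    return net, expr, truth


def figure_toy_network() -> BackgroundNetwork:
    """Six-node worked example: directed 1->2 and 5->6 (pathway), undirected
    {2,3} and {4,5} (binding). Node 3 is downstream of node 1 at distance 2;
    node 4 is upstream of node 6 at distance 2."""
    net = BackgroundNetwork()
    net.add_directed("1", "2")
    net.add_undirected("2", "3")
    net.add_undirected("4", "5")
    net.add_directed("5", "6")
    return net


def write_fixture_kgml(net: BackgroundNetwork, path, title: str = "synthetic") -> None:
    """Serialize the directed part of a network into a pathway-XML (KGML
    dialect) file the reader consumes; read(write(x)) equals the directed
    part of x."""
    root = etree.Element("pathway", name=f"path:{title}", title=title)
    nodes = sorted({n for e in net.directed_edges for n in e})
    ids = {}
    for i, g in enumerate(nodes, start=1):
        ids[g] = str(i)
        etree.SubElement(root, "entry", id=str(i), name=g, type="gene")
    for u, v in sorted(net.directed_edges):
        rel = etree.SubElement(root, "relation", entry1=ids[u], entry2=ids[v],
                               type="PPrel")
        etree.SubElement(rel, "subtype", name="activation", value="-->")
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_groups(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        for s in expr.samples:
            fh.write(f"{s}\t{expr.groups[s]}\n")


def write_ground_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
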