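"""End-to-end pipeline: network -> distances -> dynamic -> rank -> significance.

Every stage writes a plain-text artifact plus a JSON sidecar echoing the
configuration, seed, package version and input checksums, so a run can be
resumed from any stage and audited afterwards.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .distance import all_pairs, write_distance_table
from .dynamic import build_dynamic_network, load_expression, write_dynamic_network
from .network_io import merge, read_edge_list, read_network, read_pathway_xml, \
    write_edge_list, write_graphml
from .significance import empirical_pvalues
from .tspr import TSPRConfig, build_transition, fold_change, tspr_run

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and parameters of a full run; defaults are the method's
    conventional values (|PCC| > 0.7, beta 0.2, tol 1e-5, cap 15)."""

    kgml_files: list = field(default_factory=list)
    pathway_edges: str | None = None  # directed edge-list TSV alternative
    ppi_edges: str | None = None
    network: str | None = None  # pre-built network (TSV/GraphML)
    expression: str | None = None
    groups: str | None = None
    outdir: str = "infrank_out"
    pcc_threshold: float = 0.7
    beta: float = 0.2
    tol: float = 1e-5
    max_iter: int = 1000
    cap: int = 15
    topic_mode: str = "abslog2fc"
    pcc_samples: str = "all"
    n_perm: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(path, cfg: RunConfig, stage: str, **extra) -> None:
    meta = {
        "stage": stage,
        "infrank_version": __version__,
        "config": dataclasses.asdict(cfg),
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline and return the output directory.

    Stages: build-network, distances, dynamic, rank, and (when n_perm > 0)
    significance. Identical inputs + config + seed give byte-identical
    outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return deco

    @stage("build-network")
    def net():
        parts = []
        if cfg.network:
            checksums["network"] = _sha256(cfg.network)
            parts.append(read_network(cfg.network))
        if cfg.kgml_files:
            for f in cfg.kgml_files:
                checksums[str(f)] = _sha256(f)
            parts.append(read_pathway_xml(cfg.kgml_files))
        if cfg.pathway_edges:
            checksums["pathway_edges"] = _sha256(cfg.pathway_edges)
            parts.append(read_edge_list(cfg.pathway_edges, directed=True))
        if cfg.ppi_edges:
            checksums["ppi_edges"] = _sha256(cfg.ppi_edges)
            parts.append(read_edge_list(cfg.ppi_edges, directed=False))
        if not parts:
            raise ValueError("no network inputs configured")
        merged = merge(parts)
        write_edge_list(merged, out / "network.tsv")
        write_graphml(merged, out / "network.graphml")
        _sidecar(out / "network.json", cfg, "build-network",
                 inputs=checksums, nodes=len(merged.nodes),
                 directed_edges=len(merged.directed_edges),
                 undirected_edges=len(merged.undirected_edges))
        logger.info("background network: %d nodes, %d edges",
                    len(merged.nodes), merged.n_edges)
        return merged

    @stage("distances")
    def dist():
        table = all_pairs(net, cap=cfg.cap)
        write_distance_table(table, out / "distances.tsv")
        _sidecar(out / "distances.json", cfg, "distances",
                 pairs=len(table.entries), cap=cfg.cap)
        return table

    @stage("dynamic")
    def dyn():
        if not cfg.expression:
            raise ValueError("no expression matrix configured")
        checksums["expression"] = _sha256(cfg.expression)
        if cfg.groups:
            checksums["groups"] = _sha256(cfg.groups)
        expr = load_expression(cfg.expression, cfg.groups)
        d = build_dynamic_network(net, dist, expr,
                                  pcc_threshold=cfg.pcc_threshold,
                                  pcc_samples=cfg.pcc_samples)
        write_dynamic_network(d, out / "dynamic.tsv")
        _sidecar(out / "dynamic.json", cfg, "dynamic",
                 inputs=checksums, retained_pairs=len(d.edges),
                 candidate_pairs=len(dist.entries),
                 universe=len(d.node_universe))
        logger.info("dynamic network: %d of %d pairs retained",
                    len(d.edges), len(dist.entries))
        return d, expr

    dyn_net, expr = dyn

    @stage("rank")
    def result():
        tspr_cfg = TSPRConfig(beta=cfg.beta, tol=cfg.tol, max_iter=cfg.max_iter)
        topic = fold_change(expr, mode=cfg.topic_mode)
        res = tspr_run(build_transition(dyn_net), topic, tspr_cfg)
        with open(out / "scores.tsv", "w") as fh:
            fh.write("# gene\tscore\trank\n")
            for g in sorted(res.ranks, key=res.ranks.get):
                fh.write(f"{g}\t{res.scores[g]:.10g}\t{res.ranks[g]}\n")
        _sidecar(out / "scores.json", cfg, "rank",
                 iterations=res.iterations, converged=res.converged,
                 final_mais=res.mais_trace[-1] if res.mais_trace else None)
        logger.info("ranked %d genes in %d iterations (converged=%s)",
                    len(res.scores), res.iterations, res.converged)
        return res

    if cfg.n_perm > 0:
        @stage("significance")
        def _sig():
            tspr_cfg = TSPRConfig(beta=cfg.beta, tol=cfg.tol,
                                  max_iter=cfg.max_iter)
            topic = fold_change(expr, mode=cfg.topic_mode)
            perm = empirical_pvalues(dyn_net, topic, tspr_cfg,
                                     n_perm=cfg.n_perm, seed=cfg.seed)
            with open(out / "significance.tsv", "w") as fh:
                fh.write("# gene\tscore\tn\tp\n")
                for g in sorted(perm.pvalues, key=lambda x: perm.pvalues[x]):
                    fh.write(f"{g}\t{perm.observed[g]:.10g}\t"
                             f"{perm.null_exceed_counts[g]}\t{perm.pvalues[g]:.6g}\n")
            _sidecar(out / "significance.json", cfg, "significance",
                     n_perm=cfg.n_perm, seed=cfg.seed)

    return out
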