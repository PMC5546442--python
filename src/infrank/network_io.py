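"""Reading, merging and writing the static background network.

The background network mixes two kinds of evidence over gene symbols:
directed regulatory edges from curated pathway maps (KGML files) and
undirected physical-binding edges from binary protein-interaction screens.
Both are kept in one :class:`BackgroundNetwork`; the provenance of every
edge is recorded so downstream modules can distinguish them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundNetwork",
    "read_pathway_xml",
    "read_edge_list",
    "read_alias_table",
    "merge",
    "write_edge_list",
    "write_graphml",
    "read_graphml",
    "read_network",
]


@dataclass
class BackgroundNetwork:
    """Mixed directed/undirected interaction network over gene symbols.

    ``directed_edges`` holds ordered pairs (u, v) meaning "u regulates v";
    ``undirected_edges`` holds canonically ordered pairs (min, max) meaning
    "u binds v". A pair may appear in both sets; their provenances are kept
    apart. Self-loops are never stored.
    """

    nodes: set = field(default_factory=set)
    directed_edges: set = field(default_factory=set)
    undirected_edges: set = field(default_factory=set)
    edge_source: dict = field(default_factory=dict)

    def add_directed(self, u: str, v: str, source: str = "pathway") -> bool:
        if u == v:
            return False
        self.nodes.update((u, v))
        self.directed_edges.add((u, v))
        self.edge_source.setdefault(("directed", u, v), source)
        return True

    def add_undirected(self, u: str, v: str, source: str = "ppi") -> bool:
        if u == v:
            return False
        a, b = sorted((u, v))
        self.nodes.update((a, b))
        self.undirected_edges.add((a, b))
        self.edge_source.setdefault(("undirected", a, b), source)
        return True

    def has_undirected(self, u: str, v: str) -> bool:
        a, b = sorted((u, v))
        return (a, b) in self.undirected_edges

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def successors(self, u: str) -> set:
        """Nodes reachable from ``u`` in one admissible step (directed
        forward or undirected either way)."""
        out = {v for (a, v) in self.directed_edges if a == u}
        for a, b in self.undirected_edges:
            if a == u:
                out.add(b)
            elif b == u:
                out.add(a)
        return out

    def adjacency(self) -> dict:
        """Admissible-step adjacency map node -> set of successors.

        Precomputed form of :meth:`successors` for whole-network traversals.
        """
        adj: dict = {n: set() for n in self.nodes}
        for u, v in self.directed_edges:
            adj[u].add(v)
        for a, b in self.undirected_edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def directed_adjacency(self) -> dict:
        adj: dict = {n: set() for n in self.nodes}
        for u, v in self.directed_edges:
            adj[u].add(v)
        return adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BackgroundNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.directed_edges == other.directed_edges
            and self.undirected_edges == other.undirected_edges
        )


class PathwayParseError(ValueError):
    """Raised when a pathway XML file cannot be parsed."""


def _resolve_entry_genes(entry, aliases: Mapping[str, str] | None) -> list:
    """Gene identifiers carried by a KGML ``entry`` element.

    Entry names may hold several whitespace-separated identifiers; each is
    mapped through the optional alias table.
    """
    names = (entry.get("name") or "").split()
    if aliases:
        names = [aliases.get(n, n) for n in names]
    return names


def read_pathway_xml(
    files: Iterable, aliases: Mapping[str, str] | None = None
) -> BackgroundNetwork:
    """Parse pathway XML files (KGML dialect) into a directed network.

    Each ``relation`` between two gene ``entry`` elements becomes a directed
    edge entry1 -> entry2. Entries whose type is not ``gene`` (groups, maps,
    compounds) are skipped together with any relation touching them.
    Duplicate edges across files are merged.

    Parameters
    ----------
    files
        Paths of pathway XML files.
    aliases
        Optional identifier -> symbol mapping applied at read time.
    """
    net = BackgroundNetwork()
    for path in files:
        path = Path(path)
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise PathwayParseError(f"malformed pathway XML in {path}: {exc}") from exc
        root = tree.getroot()
        genes_by_id: dict = {}
        for entry in root.iter("entry"):
            if entry.get("type") == "gene":
                genes_by_id[entry.get("id")] = _resolve_entry_genes(entry, aliases)
        n_rel = 0
        for rel in root.iter("relation"):
            src = genes_by_id.get(rel.get("entry1"))
            dst = genes_by_id.get(rel.get("entry2"))
            if not src or not dst:
                continue  # non-gene endpoint: edge skipped, node not added
            for u in src:
                for v in dst:
                    if net.add_directed(u, v, source="pathway"):
                        n_rel += 1
        if n_rel == 0:
            logger.warning("pathway file %s contributed zero gene relations", path)
    return net


def read_alias_table(path) -> dict:
    """Two-column TSV mapping identifier -> symbol."""
    aliases = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 2:
                aliases[cols[0]] = cols[1]
    return aliases


def read_edge_list(
    path, directed: bool, source: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> BackgroundNetwork:
    """Read a 2-3 column TSV edge list (third column: provenance tag).

    Self-loops are dropped and counted in the log. Lines starting with '#'
    are comments.
    """
    net = BackgroundNetwork()
    default_source = source or ("pathway" if directed else "ppi")
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns")
            u, v = cols[0], cols[1]
            if aliases:
                u, v = aliases.get(u, u), aliases.get(v, v)
            tag = cols[2] if len(cols) >= 3 else default_source
            if u == v:
                dropped += 1
                continue
            if directed:
                net.add_directed(u, v, source=tag)
            else:
                net.add_undirected(u, v, source=tag)
    if dropped:
        logger.info("%s: dropped %d self-loop(s)", path, dropped)
    return net


def merge(nets: Iterable) -> BackgroundNetwork:
    """Union of node sets and both edge sets; provenance preserved.

    Idempotent, commutative and associative up to set equality.
    """
    out = BackgroundNetwork()
    for net in nets:
        out.nodes |= net.nodes
        out.directed_edges |= net.directed_edges
        out.undirected_edges |= net.undirected_edges
        for key, tag in net.edge_source.items():
            out.edge_source.setdefault(key, tag)
    return out


def write_edge_list(net: BackgroundNetwork, path) -> None:
    """3-column TSV: source, target, direction:provenance."""
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tkind\n")
        for u, v in sorted(net.directed_edges):
            tag = net.edge_source.get(("directed", u, v), "pathway")
            fh.write(f"{u}\t{v}\tdirected:{tag}\n")
        for a, b in sorted(net.undirected_edges):
            tag = net.edge_source.get(("undirected", a, b), "ppi")
            fh.write(f"{a}\t{b}\tundirected:{tag}\n")


def read_network(path) -> BackgroundNetwork:
    """Read a network written by :func:`write_edge_list` or GraphML."""
    path = Path(path)
    if path.suffix == ".graphml":
        return read_graphml(path)
    net = BackgroundNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            u, v, kind = cols[0], cols[1], cols[2]
            direction, _, tag = kind.partition(":")
            if direction == "directed":
                net.add_directed(u, v, source=tag or "pathway")
            else:
                net.add_undirected(u, v, source=tag or "ppi")
    return net


def to_networkx(net: BackgroundNetwork) -> nx.MultiDiGraph:
    """MultiDiGraph with ``direction`` and ``provenance`` edge attributes.

    Undirected edges are stored once, canonically ordered.
    """
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(net.nodes))
    for u, v in sorted(net.directed_edges):
        g.add_edge(u, v, direction="directed",
                   provenance=net.edge_source.get(("directed", u, v), "pathway"))
    for a, b in sorted(net.undirected_edges):
        g.add_edge(a, b, direction="undirected",
                   provenance=net.edge_source.get(("undirected", a, b), "ppi"))
    return g


def from_networkx(g: nx.MultiDiGraph) -> BackgroundNetwork:
    net = BackgroundNetwork()
    net.nodes.update(g.nodes())
    for u, v, data in g.edges(data=True):
        if data.get("direction") == "undirected":
            net.add_undirected(u, v, source=data.get("provenance", "ppi"))
        else:
            net.add_directed(u, v, source=data.get("provenance", "pathway"))
    return net


def write_graphml(net: BackgroundNetwork, path) -> None:
    nx.write_graphml(to_networkx(net), str(path))


def read_graphml(path) -> BackgroundNetwork:
    return from_networkx(nx.read_graphml(str(path), force_multigraph=True))
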