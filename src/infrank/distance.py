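"""Influence distance on the mixed directed/undirected background network.

The influence distance d(u -> v) is the minimal number of consecutive edge
traversals needed to reach v from u, where a directed (pathway) edge may be
crossed only in its forward orientation and an undirected (binding) edge in
either orientation. If d(u -> v) = d, then v is *downstream* of u and u is
*upstream* of v at distance d. The relation is asymmetric: a directed chain
confers downstream status only in the forward direction.

By default a path made purely of undirected edges also creates an
upstream/downstream pair; pass ``require_directed=True`` to demand at least
one directed edge on the path.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

__all__ = [
    "UNREACHABLE",
    "DistanceTable",
    "influence_distance",
    "all_pairs",
    "max_distance",
    "write_distance_table",
    "read_distance_table",
]

#: Sentinel returned when no admissible path within the cap exists.
UNREACHABLE = "unreachable"

DEFAULT_CAP = 15


@dataclass
class DistanceTable:
    """Sparse map (upstream, downstream) -> minimal influence distance.

    Only pairs with distance <= ``cap`` are stored; unreachable pairs are
    absent. Distances are >= 1 and (u, u) is never stored.
    """

    entries: dict = field(default_factory=dict)
    cap: int = DEFAULT_CAP

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, u, v):
        return self.entries.get((u, v))

    def restrict(self, cap: int) -> "DistanceTable":
        """Restriction to pairs at distance <= cap (used for the IR_k runs)."""
        return DistanceTable(
            entries={p: d for p, d in self.entries.items() if d <= cap},
            cap=min(cap, self.cap),
        )

    def downstream_of(self, u) -> dict:
        return {v: d for (a, v), d in self.entries.items() if a == u}


def _bfs_from(source, adj: dict, dadj: dict | None, cap: int) -> dict:
    """Single-source BFS over the admissible-step relation.

    When ``dadj`` is given, the search runs over states (node, crossed a
    directed edge yet) and a node counts as reached only once a directed
    edge lies on the path.
    """
    dist: dict = {}
    if dadj is None:
        seen = {source}
        frontier = deque([(source, 0)])
        while frontier:
            node, d = frontier.popleft()
            if d >= cap:
                continue
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    dist[nxt] = d + 1
                    frontier.append((nxt, d + 1))
        return dist
    # state space: (node, has_directed)
    seen = {(source, False)}
    frontier = deque([(source, False, 0)])
    while frontier:
        node, flag, d = frontier.popleft()
        if d >= cap:
            continue
        for nxt in adj[node]:
            nflag = flag or nxt in dadj[node]
            state = (nxt, nflag)
            if state not in seen:
                seen.add(state)
                if nflag and nxt not in dist:
                    dist[nxt] = d + 1
                frontier.append((nxt, nflag, d + 1))
    return dist


def influence_distance(net, source, target, cap: int = DEFAULT_CAP,
                       require_directed: bool = False):
    """Minimal admissible-path length from ``source`` to ``target``.

    Returns :data:`UNREACHABLE` when no admissible path of length <= cap
    exists. On a mixed network a path may chain directed steps (forward
    only) and undirected steps freely; e.g. with directed 1->2 and
    undirected {2,3}, node 3 is downstream of node 1 at distance 2.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for g in (source, target):
        if g not in net.nodes:
            raise KeyError(f"unknown gene {g!r}")
    adj = net.adjacency()
    dadj = net.directed_adjacency() if require_directed else None
    dist = _bfs_from(source, adj, dadj, cap)
    return dist.get(target, UNREACHABLE)


def all_pairs(net, cap: int = DEFAULT_CAP, require_directed: bool = False) -> DistanceTable:
    """All ordered pairs at influence distance <= cap, by BFS per source."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    adj = net.adjacency()
    dadj = net.directed_adjacency() if require_directed else None
    entries: dict = {}
    for source in net.nodes:
        for target, d in _bfs_from(source, adj, dadj, cap).items():
            if target != source:
                entries[(source, target)] = d
    return DistanceTable(entries=entries, cap=cap)


def max_distance(table: DistanceTable) -> int:
    """Largest stored distance (full-scale merged networks top out around 15)."""
    if not table.entries:
        raise ValueError("empty distance table")
    return max(table.entries.values())


def write_distance_table(table: DistanceTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tdistance\n")
        for (u, v), d in sorted(table.entries.items()):
            fh.write(f"{u}\t{v}\t{d}\n")


def read_distance_table(path, cap: int | None = None) -> DistanceTable:
    entries: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            u, v, d = line.split("\t")
            entries[(u, v)] = int(d)
    if cap is None:
        cap = max(entries.values()) if entries else DEFAULT_CAP
    return DistanceTable(entries=entries, cap=cap)
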