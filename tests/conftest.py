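import numpy as np
import pytest

import infrank as ir
from infrank.dynamic import DynamicNetwork, DynEdge
from infrank.network_io import BackgroundNetwork


@pytest.fixture
def toy_net():
    """The six-node mixed worked-example network."""
    return ir.figure_toy_network()


@pytest.fixture
def toy_expr():
    """Small deterministic expression matrix with tumor/normal labels."""
    import pandas as pd

    rng = np.random.default_rng(1234)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"T{i}" for i in range(5)] + [f"N{i}" for i in range(5)]
    data = pd.DataFrame(rng.uniform(10, 1000, size=(6, 10)),
                        index=genes, columns=samples)
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    return ir.ExpressionMatrix(data=data, groups=groups)


def random_mixed_network(rng, n_nodes=8, p_dir=0.15, p_undir=0.15):
    """Seeded random mixed directed/undirected network on n_nodes."""
    nodes = [str(i) for i in range(n_nodes)]
    net = BackgroundNetwork()
    net.nodes.update(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            r = rng.random()
            if r < p_dir:
                if rng.random() < 0.5:
                    net.add_directed(u, v)
                else:
                    net.add_directed(v, u)
            elif r < p_dir + p_undir:
                net.add_undirected(u, v)
    return net


def random_dynamic_network(rng, n_nodes=10, p_edge=0.3):
    """Seeded random weighted dynamic network (weights in (0, 1])."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = {}
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p_edge:
                d = int(rng.integers(1, 4))
                r = float(rng.uniform(0.70, 1.0)) * (1 if rng.random() < 0.5 else -1)
                edges[(u, v)] = DynEdge(pcc=r, distance=d, weight=abs(r) / d)
    return DynamicNetwork(edges=edges, node_universe=set(nodes))


def brute_force_influence_distance(net, source, target, cap=50):
    """Exhaustive enumeration of simple admissible paths (test oracle)."""
    adj = net.adjacency()
    best = [None]

    def walk(node, depth, visited):
        if best[0] is not None and depth >= best[0]:
            return
        if depth >= cap:
            return
        for nxt in adj[node]:
            if nxt == target:
                if best[0] is None or depth + 1 < best[0]:
                    best[0] = depth + 1
            elif nxt not in visited:
                walk(nxt, depth + 1, visited | {nxt})

    walk(source, 0, {source})
    return best[0] if best[0] is not None else ir.UNREACHABLE
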