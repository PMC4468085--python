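"""Independent brute-force oracles shared by the test suite."""

import itertools

import networkx as nx
import numpy as np


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Betweenness by exhaustive simple-path enumeration.

    All simple paths between every pair are enumerated, minimal-weight ones
    retained, and the through-node fractions accumulated with per-component
    (N-1)(N-2)/2 normalization.  Exponential; for graphs of <= 8 nodes only.
    """
    nodes = list(graph.nodes)
    out = {v: 0.0 for v in nodes}
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=nodes.index)
        n = len(members)
        if n < 3:
            continue
        norm = (n - 1) * (n - 2) / 2.0
        for j, k in itertools.combinations(members, 2):
            paths = []
            for p in nx.all_simple_paths(graph, j, k):
                w = sum(graph[a][b]["weight"] for a, b in zip(p, p[1:]))
                paths.append((w, p))
            best = min(w for w, _ in paths)
            shortest = [p for w, p in paths if w <= best * (1 + 1e-12) + 1e-12]
            for i in members:
                if i in (j, k):
                    continue
                through = sum(1 for p in shortest if i in p[1:-1])
                out[i] += through / len(shortest) / norm
    return out


def random_weighted_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """Random graph with uniform(0.1, 2) weights and ~50% edge density."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.5:
            g.add_edge(i, j, weight=float(rng.uniform(0.1, 2.0)))
    return g
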