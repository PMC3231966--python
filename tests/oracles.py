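"""Brute-force reference implementations used only by the tests.

These recompute the structural indices by direct enumeration (walks, shortest
paths, BFS distance sums) on small graphs, independently of the package's
sparse-matrix / igraph code paths.
"""

from itertools import combinations

import networkx as nx
import numpy as np


def walk_effect_matrix(G, m):
    """m-step effect by explicit walk enumeration.

    entry [i][j] = sum over all walks i = v0, v1, ..., vm = j of the product
    of 1/deg(v_k) for k = 0..m-1 (the receiver-side degrees along the walk).
    """
    nodes = sorted(G.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    out = np.zeros((n, n))

    def extend(walk, prod):
        v = walk[-1]
        if len(walk) == m + 1:
            out[idx[walk[0]], idx[v]] += prod
            return
        d = G.degree(v)
        for w in G.neighbors(v):
            extend(walk + [w], prod / d)

    for v in nodes:
        extend([v], 1.0)
    return nodes, out


def brute_topological_importance(G, n):
    """TI^n by averaging column sums of walk-enumerated effect matrices."""
    nodes = sorted(G.nodes)
    sigma = np.zeros(len(nodes))
    for m in range(1, n + 1):
        _, a = walk_effect_matrix(G, m)
        sigma += a.sum(axis=0)
    return dict(zip(nodes, sigma / n))


def brute_betweenness(G):
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    nodes = sorted(G.nodes)
    N = len(nodes)
    score = {v: 0.0 for v in nodes}
    for j, k in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, j, k))
        except nx.NetworkXNoPath:
            continue
        g_jk = len(paths)
        for i in nodes:
            if i in (j, k):
                continue
            g_jk_i = sum(i in p for p in paths)
            score[i] += g_jk_i / g_jk
    if N < 3:
        return {v: 0.0 for v in nodes}
    scale = 2.0 / ((N - 1) * (N - 2))
    return {v: s * scale for v, s in score.items()}


def brute_closeness(G):
    """Wasserman–Faust closeness from per-source BFS distance sums."""
    nodes = sorted(G.nodes)
    N = len(nodes)
    out = {}
    for v in nodes:
        dist = nx.single_source_shortest_path_length(G, v)
        r = len(dist)
        if r <= 1:
            out[v] = 0.0
            continue
        out[v] = ((r - 1) / (N - 1)) * ((r - 1) / sum(dist.values()))
    return out


def connected_atlas_graphs(max_nodes=6, min_nodes=2):
    """All connected graphs with min_nodes..max_nodes nodes (graph atlas)."""
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for G in graph_atlas_g():
        n = G.number_of_nodes()
        if min_nodes <= n <= max_nodes and nx.is_connected(G):
            out.append(G)
    return out
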