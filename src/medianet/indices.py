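"""Per-node structural indices.

Six indices are computed for every node of an undirected, unweighted simple
graph:

* ``nD``  — normalized degree, :math:`D_i/(N-1)`.
* ``nCC`` — normalized closeness, :math:`(N-1)/\\sum_j d_{ij}` on a connected
  graph; on disconnected graphs the Wasserman–Faust variant
  :math:`\\frac{r_i-1}{N-1}\\cdot\\frac{r_i-1}{\\sum_{j\\,\\mathrm{reachable}} d_{ij}}`
  where :math:`r_i` counts the nodes reachable from *i* (including *i*).
* ``nBC`` — normalized betweenness,
  :math:`2\\sum_{j<k} [g_{jk}(i)/g_{jk}] / ((N-1)(N-2))`.
* ``TI^n`` — topological importance: the one-step effect of *j* on its
  neighbour *i* is :math:`a_{1,ij} = 1/D_i`; multi-step effects are
  multiplicative along walks and additive across walks, so the *m*-step
  effect matrix is the matrix power :math:`a_m = a_1^m`.  The effect
  originated by node *i* in *m* steps is the column sum
  :math:`\\sigma_{m,i} = \\sum_j a_{m,ji}`, and
  :math:`TI^n_i = \\frac{1}{n}\\sum_{m=1}^n \\sigma_{m,i}`.
* ``TO^n_t`` — summed topological overlap: with the cumulative averaged
  effect :math:`E = \\frac{1}{n}\\sum_{m=1}^n a_m`, the strong interactors of
  *i* are :math:`S_i = \\{j \\ne i : E_{ji} > t\\}` (nodes receiving more than
  the threshold *t* of effect from *i*); :math:`TO^n_{t,ij} = |S_i \\cap S_j|`
  and :math:`TO^n_{t,i} = \\sum_{j \\ne i} TO^n_{t,ij}`.

Degree, closeness and betweenness are standard centralities and are
delegated to igraph's C routines (important for null-model ensembles on
thousand-node graphs); TI and TO are computed here with sparse matrix
algebra.  Isolated nodes take the zero-value convention for every index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "EffectMatrix",
    "node_order",
    "normalized_degree",
    "normalized_betweenness",
    "normalized_closeness",
    "one_step_matrix",
    "effect_matrix",
    "topological_importance",
    "topological_overlap",
    "compute_all",
    "index_columns",
]


def node_order(net: nx.Graph) -> list:
    """Deterministic node ordering (sorted by node identifier)."""
    return sorted(net.nodes)


def index_columns(n: int = 3, thresholds=(0.01, 0.005)) -> list[str]:
    """Column names of an index table for the given step count/thresholds."""
    return ["nD", "nCC", "nBC", f"TI{n}"] + [f"TO{n}_{t:g}" for t in thresholds]


def _to_igraph(net: nx.Graph, order: list) -> ig.Graph:
    idx = {v: i for i, v in enumerate(order)}
    return ig.Graph(n=len(order), edges=[(idx[u], idx[v]) for u, v in net.edges])


def normalized_degree(net: nx.Graph) -> dict:
    """nD_i = D_i / (N - 1); requires N >= 2."""
    N = net.number_of_nodes()
    if N < 2:
        raise ValueError("normalized degree requires at least 2 nodes")
    return {v: net.degree(v) / (N - 1) for v in node_order(net)}


def normalized_betweenness(net: nx.Graph) -> dict:
    """Normalized shortest-path betweenness; all zeros when N < 3.

    Pairs of nodes in different components contribute nothing.
    """
    order = node_order(net)
    N = len(order)
    if N < 3:
        return {v: 0.0 for v in order}
    bc = _to_igraph(net, order).betweenness(directed=False)
    scale = 2.0 / ((N - 1) * (N - 2))
    return {v: b * scale for v, b in zip(order, bc)}


def normalized_closeness(net: nx.Graph) -> dict:
    """Closeness centrality with the Wasserman–Faust component correction.

    On a connected graph this is exactly (N-1)/sum_j d_ij; isolated nodes
    get 0.  igraph's within-component closeness (r_i - 1)/sum_j d_ij is
    rescaled by the reachable-fraction factor (r_i - 1)/(N - 1).
    """
    order = node_order(net)
    N = len(order)
    if N < 2:
        raise ValueError("normalized closeness requires at least 2 nodes")
    g = _to_igraph(net, order)
    cc = np.asarray(g.closeness(normalized=True), dtype=float)
    comp = g.connected_components()
    sizes = np.asarray([len(c) for c in comp])
    r = sizes[np.asarray(comp.membership)]
    cc = np.nan_to_num(cc, nan=0.0) * (r - 1) / (N - 1)
    return dict(zip(order, cc))


@dataclass
class EffectMatrix:
    """Per-step effect matrices a_m and their cumulative average.

    ``per_step[m-1][i, j]`` is the effect of node ``nodes[j]`` on node
    ``nodes[i]`` in exactly ``m`` steps; ``cumulative`` is
    ``sum(per_step) / order``.  Rows of non-isolated nodes sum to 1 in every
    ``a_m`` (the received effect psi is 1); rows of isolated nodes are zero.
    """

    nodes: list
    per_step: list = field(repr=False)
    cumulative: sp.csr_matrix = field(repr=False)

    @property
    def order(self) -> int:
        return len(self.per_step)


def one_step_matrix(net: nx.Graph) -> EffectMatrix:
    """One-step effect matrix: a_{1,ij} = 1/D_i on edges, zero otherwise."""
    return effect_matrix(net, 1)


def effect_matrix(net: nx.Graph, n: int) -> EffectMatrix:
    """Effect matrices a_m = a_1^m for m = 1..n and their average."""
    if n < 1:
        raise ValueError("step count n must be >= 1")
    order = node_order(net)
    if not order:
        empty = sp.csr_matrix((0, 0))
        return EffectMatrix(order, [empty.copy() for _ in range(n)], empty)
    A = nx.to_scipy_sparse_array(net, nodelist=order, dtype=float, format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    a1 = sp.diags(inv) @ A
    a1 = sp.csr_matrix(a1)
    per_step = [a1]
    for _ in range(1, n):
        per_step.append(sp.csr_matrix(per_step[-1] @ a1))
    cumulative = sp.csr_matrix(sum(per_step) / n)
    return EffectMatrix(order, per_step, cumulative)


def topological_importance(net: nx.Graph, n: int = 3, em: EffectMatrix | None = None) -> dict:
    """TI^n_i: average over m = 1..n of the column sums of a_m."""
    if em is None:
        em = effect_matrix(net, n)
    elif em.order < n:
        raise ValueError("supplied EffectMatrix has too few steps")
    order = em.nodes
    if not order:
        return {}
    sigma = np.zeros(len(order))
    for m in range(n):
        sigma += np.asarray(em.per_step[m].sum(axis=0)).ravel()
    sigma /= n
    return dict(zip(order, sigma))


def _strong_interactor_matrix(em: EffectMatrix, n: int, t: float, use_cumulative: bool):
    E = em.cumulative if use_cumulative else em.per_step[n - 1]
    B = sp.csr_matrix((E > t).astype(np.int64))
    B.setdiag(0)  # a node is never its own strong interactor
    B.eliminate_zeros()
    return B


def topological_overlap(
    net: nx.Graph,
    n: int = 3,
    t: float = 0.01,
    em: EffectMatrix | None = None,
    use_cumulative: bool = True,
) -> dict:
    """Summed topological overlap TO^n_t per node (raw integer counts).

    ``use_cumulative`` selects the effect matrix defining strong
    interactors: the average over steps 1..n (default, mirroring TI's
    "up to n steps" convention) or the pure n-step matrix a_n.
    The threshold comparison is an exact ``>`` in double precision.
    """
    if t <= 0:
        raise ValueError("threshold t must be positive")
    if em is None:
        em = effect_matrix(net, n)
    elif em.order < n:
        raise ValueError("supplied EffectMatrix has too few steps")
    order = em.nodes
    if not order:
        return {}
    B = _strong_interactor_matrix(em, n, t, use_cumulative)
    # Column i of B is the indicator of S_i, so (B^T B)_{ij} = |S_i ∩ S_j|;
    # the diagonal term (j = i) is excluded from the node-wise sum.
    O = (B.T @ B).tocsr()
    to = np.asarray(O.sum(axis=1)).ravel() - O.diagonal()
    return {v: int(x) for v, x in zip(order, to)}


def compute_all(
    net: nx.Graph,
    n: int = 3,
    thresholds=(0.01, 0.005),
    use_cumulative: bool = True,
) -> pd.DataFrame:
    """All six indices for every node, one row per node.

    Returns a DataFrame indexed by node identifier (sorted, hence
    deterministic) with columns ``nD, nCC, nBC, TI<n>, TO<n>_<t>...``.
    Requires N >= 3.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("compute_all requires at least 3 nodes")
    order = node_order(net)
    em = effect_matrix(net, n)
    data = {
        "nD": normalized_degree(net),
        "nCC": normalized_closeness(net),
        "nBC": normalized_betweenness(net),
        f"TI{n}": topological_importance(net, n, em=em),
    }
    for t in thresholds:
        data[f"TO{n}_{t:g}"] = topological_overlap(
            net, n, t, em=em, use_cumulative=use_cumulative
        )
    table = pd.DataFrame(data, index=pd.Index(order, name="node"))
    return table
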