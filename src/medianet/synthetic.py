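"""Synthetic PPI instances with planted disease structure.

Emulates the statistical shape of a curated human PPI extract so that every
pipeline stage is testable without any database download: a sparse
heavy-tailed background network of ~2×10³ proteins at mean degree ≈ 3.3
(the density regime of the real mediator networks), small disjoint disease
sets (defaults 9 heart-disease, 44 diabetes, 20 obesity proteins) placed
away from each other, planted two-step mediators — some shared between the
two disease pairs (defaults 16 HD-only, 3 HO-only, 9 shared) — and
annotation terms enriched among the planted mediators.

The generator guarantees exact recoverability: after planting, every node
satisfying the two-step-mediator motif for a bridged pair is a planted
mediator of that pair (confounding motifs are rewired away), and no direct
edge links the two disease sets of a bridged pair.  Instances are pure
functions of (parameters, seed).

What this does NOT emulate: the real I2D degree distribution's exact shape,
interaction confidence scores, or biological correlation between annotation
and topology beyond the planted enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrichment import AnnotationMap
from .mediators import DiseaseSets, find_mediators

__all__ = [
    "SyntheticInstance",
    "generate_background",
    "plant_disease_structure",
    "generate_annotations",
    "generate_instance",
    "DEFAULT_SIZES",
    "DEFAULT_MEDIATORS",
]

DEFAULT_SIZES = {"H": 9, "D": 44, "O": 20}
DEFAULT_MEDIATORS = {"HD": 16, "HO": 3, "shared": 9}


@dataclass
class SyntheticInstance:
    """One generated instance with its ground truth."""

    ppi: nx.Graph
    disease_sets: DiseaseSets
    truth_mediators: dict  # (labelA, labelB) -> frozenset of planted mediators
    annotations: AnnotationMap | None
    params: dict = field(default_factory=dict)


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def generate_background(
    num_nodes: int,
    num_edges: int,
    model: str = "preferential_attachment",
    seed: int = 0,
) -> nx.Graph:
    """Sparse background network with heavy-tailed degrees and exact size.

    ``preferential_attachment`` grows a preferential-attachment tree over
    all nodes and then adds degree-proportional extra edges until exactly
    ``num_edges`` distinct edges exist (connected, heavy-tailed).
    ``configuration`` draws a discrete power-law degree sequence, builds a
    configuration-model graph, simplifies it, and adjusts the edge count to
    the exact request.  With ``num_edges == num_nodes - 1`` both models
    return the (acyclic) attachment tree.
    """
    if num_nodes < 2:
        raise ValueError("need at least 2 nodes")
    max_edges = num_nodes * (num_nodes - 1) // 2
    if not num_nodes - 1 <= num_edges <= max_edges:
        raise ValueError(
            f"num_edges={num_edges} infeasible for a near-connected simple "
            f"graph on {num_nodes} nodes"
        )
    if model not in ("preferential_attachment", "configuration"):
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    if model == "configuration" and num_edges > num_nodes - 1:
        G = _configuration_background(num_nodes, num_edges, rng)
    else:
        G = _pa_background(num_nodes, num_edges, rng)
    H = nx.Graph(name=f"synthetic_{model}")
    H.add_nodes_from(_node_name(i) for i in range(num_nodes))
    H.add_edges_from((_node_name(u), _node_name(v)) for u, v in G.edges)
    return H


def _pa_background(num_nodes: int, num_edges: int, rng) -> nx.Graph:
    G = nx.Graph()
    G.add_node(0)
    # endpoint pool with degree-proportional multiplicity
    pool = [0]
    for v in range(1, num_nodes):
        u = pool[rng.integers(len(pool))]
        G.add_edge(u, v)
        pool.extend((u, v))
    while G.number_of_edges() < num_edges:
        u = pool[rng.integers(len(pool))]
        v = pool[rng.integers(len(pool))]
        if u != v and not G.has_edge(u, v):
            G.add_edge(u, v)
            pool.extend((u, v))
    return G


def _configuration_background(num_nodes: int, num_edges: int, rng) -> nx.Graph:
    # discrete power-law degrees (exponent ~2.5), rescaled to the target sum
    raw = rng.zipf(2.5, size=num_nodes)
    raw = np.minimum(raw, num_nodes - 1)
    target_sum = 2 * num_edges
    deg = np.maximum(1, np.round(raw * target_sum / raw.sum()).astype(int))
    diff = target_sum - deg.sum()
    order = np.argsort(-deg)
    i = 0
    while diff != 0:
        j = order[i % num_nodes]
        if diff > 0:
            deg[j] += 1
            diff -= 1
        elif deg[j] > 1:
            deg[j] -= 1
            diff += 1
        i += 1
    G = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
    G = nx.Graph(G)
    G.remove_edges_from(nx.selfloop_edges(G))
    # simplification loses some edges; top up (or trim) to the exact count
    while G.number_of_edges() < num_edges:
        u, v = rng.integers(num_nodes, size=2)
        if u != v and not G.has_edge(u, v):
            G.add_edge(int(u), int(v))
    while G.number_of_edges() > num_edges:
        edges = sorted(G.edges)
        G.remove_edge(*edges[rng.integers(len(edges))])
    G.add_nodes_from(range(num_nodes))
    return G


def _pick_separated(candidates, count, net, rng, taken, min_dist=3):
    """Greedily pick nodes at pairwise distance >= min_dist where feasible."""
    excluded = set()
    for t in taken:
        excluded |= set(nx.single_source_shortest_path_length(net, t, cutoff=min_dist - 1))
    picked = []
    pool = [c for c in candidates if c not in taken]
    rng.shuffle(pool)
    for c in pool:
        if len(picked) == count:
            break
        if c not in excluded:
            picked.append(c)
            excluded |= set(
                nx.single_source_shortest_path_length(net, c, cutoff=min_dist - 1)
            )
    # fall back to any remaining candidate if separation is infeasible
    if len(picked) < count:
        for c in pool:
            if len(picked) == count:
                break
            if c not in picked:
                picked.append(c)
    if len(picked) < count:
        raise ValueError("not enough candidate nodes for the requested disease sets")
    return picked


def plant_disease_structure(
    net: nx.Graph,
    sizes: dict | None = None,
    mediators: dict | None = None,
    seed: int = 0,
) -> SyntheticInstance:
    """Plant disjoint disease sets and exactly recoverable two-step mediators.

    ``sizes`` maps disease labels H/D/O to set sizes; ``mediators`` gives the
    number of HD-only, HO-only and shared planted mediators.  The input graph
    is copied, never mutated.  Raises before any planting if the counts are
    infeasible.
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    mediators = dict(DEFAULT_MEDIATORS if mediators is None else mediators)
    n_disease = sum(sizes.values())
    n_med = mediators["HD"] + mediators["HO"] + mediators["shared"]
    if n_disease + n_med > net.number_of_nodes():
        raise ValueError(
            f"requested {n_disease} disease + {n_med} mediator nodes exceed "
            f"network size {net.number_of_nodes()}"
        )
    rng = np.random.default_rng(seed)
    G = net.copy()

    # Disease proteins: low-degree nodes, pairwise distance >= 3 where feasible
    by_degree = sorted(G.nodes, key=lambda v: (G.degree(v), v))
    candidates = [v for v in by_degree if G.degree(v) <= 4] or by_degree
    taken: set = set()
    disease: dict[str, list] = {}
    for label in sorted(sizes):
        picked = _pick_separated(candidates, sizes[label], G, rng, taken)
        disease[label] = picked
        taken |= set(picked)
    ds = DiseaseSets({label: set(p) for label, p in disease.items()})
    all_disease = ds.all_proteins()

    # Mediator nodes: anywhere outside the disease sets
    med_pool = [v for v in sorted(G.nodes) if v not in all_disease]
    rng.shuffle(med_pool)
    shared = med_pool[: mediators["shared"]]
    hd_only = med_pool[mediators["shared"]: mediators["shared"] + mediators["HD"]]
    ho_only = med_pool[
        mediators["shared"] + mediators["HD"]: mediators["shared"]
        + mediators["HD"] + mediators["HO"]
    ]
    truth = {
        ("H", "D"): frozenset(shared) | frozenset(hd_only),
        ("H", "O"): frozenset(shared) | frozenset(ho_only),
    }

    added, removed = [], []

    def _remove_edge(u, v):
        G.remove_edge(u, v)
        removed.append((u, v))

    def _add_edge(u, v):
        if not G.has_edge(u, v):
            G.add_edge(u, v)
            added.append((u, v))

    # no direct edge between the disease sets of a bridged pair
    for a, b in (("H", "D"), ("H", "O")):
        for u in sorted(ds[a]):
            for v in sorted(set(G.neighbors(u)) & ds[b]):
                _remove_edge(u, v)

    # wire each planted mediator into both sides of its pair(s)
    roles = {m: {"H"} for m in shared + hd_only + ho_only}
    for m in shared:
        roles[m] |= {"D", "O"}
    for m in hd_only:
        roles[m].add("D")
    for m in ho_only:
        roles[m].add("O")
    for m in sorted(roles):
        for side in sorted(roles[m]):
            if not set(G.neighbors(m)) & ds[side]:
                target = sorted(ds[side])[rng.integers(len(ds[side]))]
                _add_edge(m, target)
        # strip edges into disease sets the mediator must NOT bridge
        for side in sorted(set(sizes) - roles[m]):
            for v in sorted(set(G.neighbors(m)) & ds[side]):
                _remove_edge(m, v)

    # de-confound: any non-planted node matching a bridged motif is rewired.
    # Since all H–D and H–O edges were removed, disease proteins themselves
    # can never qualify; only plain nodes (or mediators of the other pair) can.
    plain = [
        v for v in sorted(G.nodes) if v not in all_disease and v not in roles
    ]
    for a, b in (("H", "D"), ("H", "O")):
        found = find_mediators(G, ds[a], ds[b], require_pair_unlinked=True)
        for m in sorted(found - truth[(a, b)]):
            # break contact with the non-H side (H contacts may be needed
            # for the node's planted role in the other pair)
            for v in sorted(set(G.neighbors(m)) & ds[b]):
                _remove_edge(m, v)
                repl = plain[rng.integers(len(plain))]
                if repl != m:
                    _add_edge(m, repl)
            if m not in roles:  # unplanted: H contacts are expendable too
                pass  # removing the b-side contact already breaks the motif

    # keep the density near the request: trim plain–plain edges to offset
    # the net addition (never touching disease- or mediator-incident edges)
    surplus = len(added) - len(removed)
    if surplus > 0:
        protected = set(all_disease) | set(roles)
        plain_edges = [
            (u, v)
            for u, v in sorted(G.edges)
            if u not in protected and v not in protected
            and G.degree(u) > 1 and G.degree(v) > 1
        ]
        rng.shuffle(plain_edges)
        for u, v in plain_edges[:surplus]:
            _remove_edge(u, v)

    for a, b in (("H", "D"), ("H", "O")):
        assert find_mediators(G, ds[a], ds[b]) == truth[(a, b)], (
            "planting failed to converge"
        )

    params = dict(
        sizes=sizes,
        mediators=mediators,
        seed=int(seed),
        edges_added=len(added),
        edges_removed=len(removed),
    )
    G.graph["name"] = "synthetic_ppi"
    return SyntheticInstance(
        ppi=G, disease_sets=ds, truth_mediators=truth, annotations=None, params=params
    )


def generate_annotations(
    instance: SyntheticInstance,
    num_terms: int = 50,
    enriched_term_fraction: float = 0.2,
    enrichment_odds: float = 10.0,
    base_rate: float = 0.05,
    seed: int = 0,
) -> AnnotationMap:
    """Assign annotation terms, enriching some among the planted mediators.

    Every (protein, term) pair is an independent Bernoulli draw at
    ``base_rate``; for the designated enriched terms the odds of annotating
    a planted mediator are multiplied by ``enrichment_odds``.  The map is
    stored on the instance (``instance.annotations``) and the enriched term
    identifiers recorded in ``instance.params["enriched_terms"]``.
    """
    if num_terms < 0 or enriched_term_fraction < 0 or enrichment_odds <= 0:
        raise ValueError("annotation parameters must be positive")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(num_terms)]
    n_enriched = int(round(num_terms * enriched_term_fraction))
    enriched = set(terms[:n_enriched])
    mediator_set = frozenset().union(*instance.truth_mediators.values()) \
        if instance.truth_mediators else frozenset()
    odds = base_rate / (1 - base_rate)
    p_enriched = (odds * enrichment_odds) / (1 + odds * enrichment_odds)
    pairs = []
    for protein in sorted(instance.ppi.nodes):
        is_med = protein in mediator_set
        for term in terms:
            p = p_enriched if (is_med and term in enriched) else base_rate
            if rng.random() < p:
                pairs.append((protein, term))
    ann = AnnotationMap(pairs)
    instance.annotations = ann
    instance.params["enriched_terms"] = sorted(enriched)
    instance.params["annotation_seed"] = int(seed)
    return ann


def generate_instance(
    num_nodes: int = 2000,
    num_edges: int = 3500,
    sizes: dict | None = None,
    mediators: dict | None = None,
    model: str = "preferential_attachment",
    num_terms: int = 50,
    enriched_term_fraction: float = 0.2,
    enrichment_odds: float = 10.0,
    seed: int = 0,
    with_annotations: bool = True,
) -> SyntheticInstance:
    """Full instance at defaults mirroring the real networks' scale."""
    ss = np.random.SeedSequence(seed)
    s_bg, s_plant, s_ann = (int(s) % (2**31) for s in ss.generate_state(3, np.uint32))
    net = generate_background(num_nodes, num_edges, model=model, seed=s_bg)
    inst = plant_disease_structure(net, sizes=sizes, mediators=mediators, seed=s_plant)
    inst.params.update(num_nodes=num_nodes, num_edges=num_edges, model=model,
                       root_seed=int(seed))
    if with_annotations:
        generate_annotations(
            inst,
            num_terms=num_terms,
            enriched_term_fraction=enriched_term_fraction,
            enrichment_odds=enrichment_odds,
            seed=s_ann,
        )
    return inst
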