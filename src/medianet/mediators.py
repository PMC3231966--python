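"""Two-step mediator proteins between disease sets and their networks.

A mediator of a disease pair (A, B) is a protein outside both sets that is
directly connected to at least one protein of each set — bridging the sets
via a length-2 path.  By default a further condition applies: at least one
bridged (a, b) pair must have no direct a–b interaction (the mediator
connects proteins that are "otherwise unconnected").  Chains of longer
mediated paths are deliberately out of scope.

From a mediator set two networks are derived (and, across pairs, their
aggregate):

* the *mediator network* — the induced subgraph on the mediators plus all
  of their direct neighbours;
* the *mediator subnetwork* — the induced subgraph on the mediators alone;
* the *total network* — the union of the per-pair mediator networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph_core import induced_subgraph, union

__all__ = [
    "DiseaseSets",
    "MediatorResult",
    "read_disease_sets",
    "find_mediators",
    "build_mediator_network",
    "build_all",
    "summarize",
]


class DiseaseSets:
    """Named, pairwise-disjoint protein sets (e.g. H, D, O)."""

    def __init__(self, sets: dict):
        sets = {label: frozenset(p) for label, p in sets.items()}
        seen: dict[str, str] = {}
        for label, proteins in sets.items():
            for p in proteins:
                if p in seen:
                    raise ValueError(
                        f"protein {p!r} assigned to both {seen[p]!r} and {label!r}; "
                        "disease sets must be disjoint"
                    )
                seen[p] = label
        self._sets = sets

    def __getitem__(self, label: str) -> frozenset:
        return self._sets[label]

    def __contains__(self, label: str) -> bool:
        return label in self._sets

    def __iter__(self):
        return iter(self._sets)

    def items(self):
        return self._sets.items()

    @property
    def labels(self) -> list[str]:
        return sorted(self._sets)

    def all_proteins(self) -> frozenset:
        return frozenset().union(*self._sets.values()) if self._sets else frozenset()

    def absent_from(self, net: nx.Graph) -> dict:
        """Per label, the members missing from a network's node set."""
        nodes = set(net.nodes)
        return {label: sorted(p - nodes) for label, p in self._sets.items()}


def read_disease_sets(path) -> DiseaseSets:
    """Read 'protein_id<TAB>label' lines into a :class:`DiseaseSets`."""
    sets: dict[str, set] = {}
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'protein_id\\tlabel'")
            sets.setdefault(fields[1], set()).add(fields[0])
    return DiseaseSets(sets)


@dataclass
class MediatorResult:
    """Mediators of one disease pair and the two networks built from them."""

    pair: tuple
    mediators: frozenset
    mediator_network: nx.Graph
    mediator_subnetwork: nx.Graph


def find_mediators(
    ppi: nx.Graph,
    setA: frozenset | set,
    setB: frozenset | set,
    require_pair_unlinked: bool = True,
) -> frozenset:
    """Two-step mediators between two disjoint disease sets.

    A node m outside both sets qualifies when it has at least one neighbour
    in each set; with ``require_pair_unlinked`` (default) some bridged
    (a, b) neighbour pair must additionally lack a direct a–b edge.
    """
    setA, setB = frozenset(setA), frozenset(setB)
    if setA & setB:
        raise ValueError(f"disease sets overlap: {sorted(setA & setB)}")
    disease = setA | setB
    candidates = set()
    for s in disease & set(ppi.nodes):
        candidates.update(ppi.neighbors(s))
    candidates -= disease
    mediators = set()
    for m in candidates:
        nbrs = set(ppi.neighbors(m))
        contacts_a = nbrs & setA
        contacts_b = nbrs & setB
        if not contacts_a or not contacts_b:
            continue
        if not require_pair_unlinked:
            mediators.add(m)
            continue
        if any(
            not ppi.has_edge(a, b) for a in contacts_a for b in contacts_b
        ):
            mediators.add(m)
    return frozenset(mediators)


def build_mediator_network(ppi: nx.Graph, mediators) -> nx.Graph:
    """Induced subgraph on the mediators plus all their direct neighbours."""
    mediators = set(mediators)
    unknown = mediators - set(ppi.nodes)
    if unknown:
        raise ValueError(f"mediators not in network: {sorted(unknown)}")
    keep = set(mediators)
    for m in mediators:
        keep.update(ppi.neighbors(m))
    return induced_subgraph(ppi, keep)


def build_all(
    ppi: nx.Graph,
    ds: DiseaseSets,
    pairs: list[tuple],
    require_pair_unlinked: bool = True,
):
    """Mediator results for every disease pair plus the aggregated network.

    Returns ``(results, total, shared)`` where ``results`` maps each pair to
    its :class:`MediatorResult`, ``total`` is the union of the per-pair
    mediator networks, and ``shared`` is the set of mediators common to all
    pairs (proteins bridging every analysed disease pair).
    """
    for a, b in pairs:
        for label in (a, b):
            if label not in ds:
                raise KeyError(f"unknown disease label {label!r}")
    results = {}
    for a, b in pairs:
        meds = find_mediators(ppi, ds[a], ds[b], require_pair_unlinked)
        net = build_mediator_network(ppi, meds)
        net.graph["name"] = f"{a}{b}"
        sub = induced_subgraph(ppi, meds)
        sub.graph["name"] = f"{a}{b}_mediators"
        results[(a, b)] = MediatorResult((a, b), meds, net, sub)
    total = union([r.mediator_network for r in results.values()], name="total")
    shared = (
        frozenset.intersection(*(r.mediators for r in results.values()))
        if results
        else frozenset()
    )
    return results, total, shared


def summarize(results: dict, total: nx.Graph) -> pd.DataFrame:
    """Size bookkeeping for the per-pair networks and the total network.

    One row per network with node count N, link count L, mediator and
    neighbour counts; for the total network also the counts of nodes shared
    between all per-pair networks and exclusive to each.
    """
    rows = []
    for (a, b), res in results.items():
        name = f"{a}{b}"
        n_med = len(res.mediators)
        rows.append(
            {
                "network": name,
                "N": res.mediator_network.number_of_nodes(),
                "L": res.mediator_network.number_of_edges(),
                "mediators": n_med,
                "neighbours": res.mediator_network.number_of_nodes() - n_med,
                "shared_nodes": "",
                "exclusive_nodes": "",
            }
        )
        rows.append(
            {
                "network": f"{name}_mediators",
                "N": res.mediator_subnetwork.number_of_nodes(),
                "L": res.mediator_subnetwork.number_of_edges(),
                "mediators": n_med,
                "neighbours": 0,
                "shared_nodes": "",
                "exclusive_nodes": "",
            }
        )
    node_sets = {pair: set(r.mediator_network.nodes) for pair, r in results.items()}
    shared_nodes = set.intersection(*node_sets.values()) if node_sets else set()
    all_meds = (
        frozenset().union(*(r.mediators for r in results.values()))
        if results
        else frozenset()
    )
    exclusive = {
        pair: len(nodes - set().union(*(o for p, o in node_sets.items() if p != pair)))
        if len(node_sets) > 1
        else len(nodes)
        for pair, nodes in node_sets.items()
    }
    rows.append(
        {
            "network": "total",
            "N": total.number_of_nodes(),
            "L": total.number_of_edges(),
            "mediators": len(all_meds & set(total.nodes)),
            "neighbours": total.number_of_nodes() - len(all_meds & set(total.nodes)),
            "shared_nodes": len(shared_nodes),
            "exclusive_nodes": ";".join(
                f"{a}{b}:{exclusive[(a, b)]}" for (a, b) in results
            ),
        }
    )
    return pd.DataFrame(rows)
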