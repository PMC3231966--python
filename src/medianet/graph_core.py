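"""Graph data model, file I/O and basic operations shared by all stages.

Networks are plain :class:`networkx.Graph` objects: undirected, unweighted,
simple (no self-loops, no parallel edges), with protein identifiers as
opaque, case-sensitive string node labels.  Isolated nodes are legal and
representable.  An optional human-readable name is stored under
``G.graph["name"]``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("medianet")

__all__ = [
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "induced_subgraph",
    "union",
    "shortest_path_lengths",
]


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _split_fields(line: str) -> list[str]:
    # Tab-delimited when tabs are present, otherwise any whitespace (SIF
    # files in the wild use both).
    return line.split("\t") if "\t" in line else line.split()


def read_edge_list(path, dialect: str = "tsv2col", name: str | None = None) -> nx.Graph:
    """Read an undirected network from a text edge list.

    Parameters
    ----------
    path : path-like
        File to read.  Blank lines and lines starting with ``#`` are ignored.
    dialect : {"tsv2col", "sif"}
        ``tsv2col``: two tab-separated identifier columns per line.
        ``sif``: ``source  relation  target [target ...]``; the relation
        token is ignored and the line fans out to one edge per target.  A
        lone identifier on a line declares an isolated node.
    name : str, optional
        Label stored on the returned graph (defaults to the file stem).

    Returns
    -------
    networkx.Graph
        Deduplicated simple graph.  Self-loops are dropped with a logged
        count; node identifiers are taken verbatim (case-sensitive).

    Raises
    ------
    EdgeListParseError
        On a malformed line (reports the 1-based line number).
    """
    path = Path(path)
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    G = nx.Graph(name=name if name is not None else path.stem)
    n_self_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if dialect == "tsv2col":
                if len(fields) < 2:
                    raise EdgeListParseError(
                        path, lineno, f"expected 2 tab-separated columns, got {len(fields)}"
                    )
                pairs = [(fields[0], fields[1])]
            else:  # sif
                if len(fields) == 1:
                    G.add_node(fields[0])
                    continue
                if len(fields) == 2:
                    raise EdgeListParseError(
                        path, lineno, "SIF line with a relation but no target"
                    )
                src = fields[0]
                pairs = [(src, tgt) for tgt in fields[2:]]
            for u, v in pairs:
                if u == v:
                    n_self_loops += 1
                    G.add_node(u)
                else:
                    G.add_edge(u, v)
    if n_self_loops:
        logger.info("read_edge_list(%s): dropped %d self-loop(s)", path, n_self_loops)
    return G


def write_edge_list(net: nx.Graph, path, dialect: str = "tsv2col") -> None:
    """Write a network as a canonical (sorted) edge list.

    Edges are written once each with endpoints in sorted order, lines sorted;
    re-reading the file reproduces the same (nodes, edges) pair.  In the
    ``tsv2col`` dialect isolated nodes cannot be represented and are dropped
    with a warning; the ``sif`` dialect writes them as lone-identifier lines.
    """
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "tsv2col":
            if isolated:
                logger.warning(
                    "write_edge_list(%s): %d isolated node(s) not representable "
                    "in tsv2col and omitted", path, len(isolated),
                )
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
        elif dialect == "sif":
            for u, v in edges:
                fh.write(f"{u}\tpp\t{v}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")


def induced_subgraph(net: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Subgraph induced on ``keep`` ∩ ``net.nodes``.

    Nodes in ``keep`` absent from ``net`` are ignored; all edges with both
    endpoints retained are kept.  Returns an independent copy.
    """
    keep = set(keep) & set(net.nodes)
    H = nx.Graph(net.subgraph(keep))
    H.graph["name"] = net.graph.get("name", "")
    return H


def union(nets: list[nx.Graph], name: str | None = None) -> nx.Graph:
    """Node-wise and edge-wise union of one or more networks."""
    if not nets:
        raise ValueError("union() requires at least one network")
    G = nx.Graph(name=name if name is not None else "union")
    for net in nets:
        G.add_nodes_from(net.nodes)
        G.add_edges_from(net.edges)
    return G


def shortest_path_lengths(net: nx.Graph, source: str) -> Mapping[str, int]:
    """BFS distances (in edge counts) from ``source``.

    Unreachable nodes are absent from the returned map; the source maps to 0.
    """
    if source not in net:
        raise KeyError(f"source node {source!r} not in network")
    return dict(nx.single_source_shortest_path_length(net, source))
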