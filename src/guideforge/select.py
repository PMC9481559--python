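"""Orthogonal set selection: maximum independent set of the interaction graph.

The maximum independent set is found as the maximum clique of the complement
graph, enumerated with networkx ``find_cliques`` (Bron-Kerbosch with
pivoting).  Candidate pools are small, so the exponential worst case is
acceptable; a node-count guard aborts rather than hang on large graphs.
Among equal-cardinality maxima the lexicographically smallest id-sorted set
is returned, making selection deterministic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class OrthogonalSet:
    member_ids: tuple
    size: int
    exhaustively_verified: bool = False


class GraphTooLargeError(RuntimeError):
    pass


def maximum_independent_set(graph: nx.Graph, max_nodes: int = 64) -> OrthogonalSet:
    """Maximum-cardinality independent set with a deterministic tie-break."""
    if any(graph.has_edge(v, v) for v in graph):
        raise ValueError("graph must have no self-loops")
    n = graph.number_of_nodes()
    if n == 0:
        return OrthogonalSet(member_ids=(), size=0)
    if n > max_nodes:
        raise GraphTooLargeError(
            f"{n} nodes exceeds the exact-MIS guard of {max_nodes}; "
            "reduce the pool or raise max_nodes"
        )
    complement = nx.complement(graph)
    complement.add_nodes_from(graph.nodes)  # keep isolated nodes
    best: tuple | None = None
    for clique in nx.find_cliques(complement):
        key = (-len(clique), tuple(sorted(clique)))
        if best is None or key < best:
            best = key
    members = best[1]
    return OrthogonalSet(member_ids=members, size=len(members))


def is_independent_set(graph: nx.Graph, ids) -> bool:
    """True iff no graph edge joins two members of ``ids``."""
    ids = list(ids)
    unknown = [v for v in ids if v not in graph]
    if unknown:
        raise KeyError(f"unknown node id(s): {unknown}")
    return not any(graph.has_edge(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :])


def write_selection_tsv(
    selected: OrthogonalSet, graph: nx.Graph, path: str | os.PathLike
) -> None:
    """Selected members plus the interaction-graph density context."""
    n = graph.number_of_nodes()
    density = nx.density(graph) if n > 1 else 0.0
    with open(path, "w") as fh:
        fh.write(f"# nodes={n}\tedges={graph.number_of_edges()}\tdensity={density:.4f}\n")
        fh.write("member_id\n")
        for member in selected.member_ids:
            fh.write(member + "\n")
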