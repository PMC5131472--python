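"""Weighted-graph model, normalization, and neighborhood queries.

Graphs are plain :class:`networkx.Graph` objects whose edges carry a strictly
positive ``weight`` attribute.  The model is an undirected weighted network
G(V, E, W): no self-loops, w_ij = w_ji, and (after :func:`normalize_weights`)
all weights in (0, 1] with max weight exactly 1.  Zero is reserved as the
sentinel weight of a non-observed link, which is why non-positive input
weights are rejected rather than dropped.

Node labels are opaque; every ordering need (tie-breaks, reproducibility)
uses the lexicographic order of the labels' string form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Iterator

import networkx as nx

Node = Hashable
Pair = tuple[Node, Node]

__all__ = [
    "NeighborSet",
    "label_key",
    "pair_key",
    "validate_graph",
    "normalize_weights",
    "neighbor_set",
    "degree",
    "strength",
]


def label_key(v: Node) -> str:
    """Deterministic sort key for an opaque node label."""
    return str(v)


def pair_key(u: Node, v: Node) -> Pair:
    """Canonical (lexicographically ordered) form of an unordered node pair."""
    return (u, v) if label_key(u) <= label_key(v) else (v, u)


def iter_pairs(nodes: Iterable[Node]) -> Iterator[Pair]:
    """All unordered pairs of distinct nodes, in lexicographic order."""
    ordered = sorted(nodes, key=label_key)
    for i, u in enumerate(ordered):
        for v in ordered[i + 1 :]:
            yield (u, v)


@dataclass(frozen=True)
class NeighborSet:
    """The neighbor set Γ(v): the nodes adjacent to a center node.

    ``degree`` is |Γ(v)| and ``strength`` is the sum of incident edge
    weights, the weighted analogue of degree.
    """

    center: Node
    members: frozenset

    @property
    def degree(self) -> int:
        return len(self.members)

    def strength(self, G: nx.Graph) -> float:
        return sum(G[self.center][u]["weight"] for u in sorted(self.members, key=label_key))


def validate_graph(G: nx.Graph) -> None:
    """Check the weighted-network invariants; raise ``ValueError`` otherwise."""
    if G.is_directed() or G.is_multigraph():
        raise ValueError("expected a simple undirected graph")
    for u, v, data in G.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop at node {u!r} is not allowed")
        w = data.get("weight")
        if w is None:
            raise ValueError(f"edge ({u!r}, {v!r}) has no weight attribute")
        if not (w > 0):
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")


def normalize_weights(G: nx.Graph) -> nx.Graph:
    """Divide every weight by the global maximum weight.

    The result has max weight exactly 1 and all weights in (0, 1].  Dividing
    by the max (rather than min-max scaling) keeps every existing link
    strictly positive, so zero stays reserved for "no link", and preserves
    the weight ratios the neighbor-set estimator is built on.  Idempotent.
    """
    validate_graph(G)
    if G.number_of_edges() == 0:
        raise ValueError("cannot normalize a graph with no edges")
    wmax = max(data["weight"] for _, _, data in G.edges(data=True))
    H = G.copy()
    for u, v, data in H.edges(data=True):
        data["weight"] = data["weight"] / wmax
    return H


def neighbor_set(G: nx.Graph, v: Node) -> NeighborSet:
    """Return Γ(v) for a node of ``G``."""
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    return NeighborSet(center=v, members=frozenset(G[v]))


def degree(G: nx.Graph, v: Node) -> int:
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    return G.degree(v)


def strength(G: nx.Graph, v: Node) -> float:
    """Node strength s_v = sum of weights of edges incident to v."""
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    return sum(G[v][u]["weight"] for u in sorted(G[v], key=label_key))
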