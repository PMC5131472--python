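"""Local similarity indices for link prediction.

Nine indices from the common-neighbors family score how likely a
non-connected node pair (x, y) is to form a link, using only the 2-hop
neighborhood.  With Z = Γ(x) ∩ Γ(y), k_z the degree and s_z the strength of
a common neighbor z (natural logs throughout):

unweighted                weighted (Murata–Moriyasu)                reliable-route
CN  = |Z|                 WCN  = Σ (w_xz + w_zy) / 2                rWCN  = Σ w_xz · w_zy
AA  = Σ 1 / log k_z       WAA  = Σ (w_xz + w_zy) / (2 log(1+s_z))   rWAA  = Σ w_xz·w_zy / log(1+s_z)
RA  = Σ 1 / k_z           WRA  = Σ (w_xz + w_zy) / (2 s_z)          rWRA  = Σ w_xz·w_zy / s_z

On an all-unit-weight graph WCN and rWCN coincide with CN, and WRA and rWRA
with RA; WAA/rWAA do not reduce to AA because of log(1+s_z) versus log k_z.
Every index is zero for pairs at distance > 2, so only distance-2
candidates are materialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx

from .graph import Node, Pair, label_key, pair_key, strength

__all__ = ["INDICES", "ScoreTable", "score_pair", "score_candidates", "top_L"]

INDICES = ("CN", "AA", "RA", "WCN", "WAA", "WRA", "rWCN", "rWAA", "rWRA")


def _terms(G: nx.Graph, x: Node, y: Node) -> list[tuple[Node, float, float]]:
    common = sorted(set(G[x]) & set(G[y]), key=label_key)
    return [(z, G[x][z]["weight"], G[z][y]["weight"]) for z in common]


def _score(G: nx.Graph, index: str, x: Node, y: Node) -> float:
    terms = _terms(G, x, y)
    if index == "CN":
        return float(len(terms))
    if index == "AA":
        return sum(1.0 / math.log(G.degree(z)) for z, _, _ in terms)
    if index == "RA":
        return sum(1.0 / G.degree(z) for z, _, _ in terms)
    if index == "WCN":
        return sum((wxz + wzy) / 2.0 for _, wxz, wzy in terms)
    if index == "WAA":
        return sum((wxz + wzy) / (2.0 * math.log1p(strength(G, z))) for z, wxz, wzy in terms)
    if index == "WRA":
        return sum((wxz + wzy) / (2.0 * strength(G, z)) for z, wxz, wzy in terms)
    if index == "rWCN":
        return sum(wxz * wzy for _, wxz, wzy in terms)
    if index == "rWAA":
        return sum(wxz * wzy / math.log1p(strength(G, z)) for z, wxz, wzy in terms)
    if index == "rWRA":
        return sum(wxz * wzy / strength(G, z) for z, wxz, wzy in terms)
    raise ValueError(f"unknown similarity index {index!r}")


def score_pair(G: nx.Graph, index: str, x: Node, y: Node) -> float:
    """Similarity score s_xy for one candidate pair under one index."""
    if x == y:
        raise ValueError("candidate pair must consist of two distinct nodes")
    for v in (x, y):
        if v not in G:
            raise KeyError(f"node {v!r} not in graph")
    return _score(G, index, x, y)


@dataclass
class ScoreTable:
    """Scores for candidate (non-edge) pairs under one similarity index.

    Only pairs with at least one common neighbor are stored; every other
    candidate implicitly scores 0.  ``nodes``/``edges`` are retained so
    :func:`top_L` can enumerate and pad over the full candidate universe
    U − E.
    """

    index: str
    scores: dict = field(default_factory=dict)
    nodes: tuple = ()
    edges: frozenset = frozenset()

    def get(self, x: Node, y: Node) -> float:
        return self.scores.get(pair_key(x, y), 0.0)

    def candidate_universe(self) -> list[Pair]:
        """All non-edge pairs U − E in lexicographic order."""
        out = []
        ordered = sorted(self.nodes, key=label_key)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                if pair_key(u, v) not in self.edges:
                    out.append((u, v))
        return out

    def to_tsv(self, path) -> None:
        ranked = sorted(self.scores.items(), key=lambda kv: (-kv[1], label_key(kv[0][0]), label_key(kv[0][1])))
        with open(path, "w", encoding="utf-8") as fh:
            for (u, v), s in ranked:
                fh.write(f"{u}\t{v}\t{s!r}\n")


def score_candidates(G: nx.Graph, index: str) -> ScoreTable:
    """Score every candidate pair of U − E that has ≥ 1 common neighbor.

    Candidates are found by walking 2-hop paths through each node, which is
    lossless (all nine indices are provably zero beyond distance 2) and
    keeps the cost at O(Σ_z k_z²).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot score candidates of an empty graph")
    if index not in INDICES:
        raise ValueError(f"unknown similarity index {index!r}")
    candidates: set[Pair] = set()
    for z in G:
        nbrs = sorted(G[z], key=label_key)
        for i, u in enumerate(nbrs):
            for v in nbrs[i + 1 :]:
                if not G.has_edge(u, v):
                    candidates.add(pair_key(u, v))
    table = ScoreTable(
        index=index,
        nodes=tuple(sorted(G.nodes(), key=label_key)),
        edges=frozenset(pair_key(u, v) for u, v in G.edges()),
    )
    for u, v in sorted(candidates, key=lambda p: (label_key(p[0]), label_key(p[1]))):
        table.scores[(u, v)] = _score(G, index, u, v)
    return table


def top_L(table: ScoreTable, L: int) -> list[Pair]:
    """The L highest-scoring candidate pairs, deterministically ordered.

    Ties break lexicographically.  If fewer than L pairs carry a positive
    score, the list is padded with the remaining (zero-score) candidates in
    lexicographic order, so the returned list always has length exactly L.
    """
    if L < 1:
        raise ValueError("L must be a positive integer")
    universe = table.candidate_universe()
    if L > len(universe):
        raise ValueError(f"L={L} exceeds the {len(universe)} candidate pairs of U − E")
    ranked = sorted(
        table.scores.items(), key=lambda kv: (-kv[1], label_key(kv[0][0]), label_key(kv[0][1]))
    )
    out = [pair for pair, _ in ranked[:L]]
    if len(out) < L:
        scored = set(table.scores)
        out.extend(p for p in universe if p not in scored)
        out = out[:L]
    return out
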