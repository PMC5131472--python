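"""Neighbor-set edge-weight prediction.

The estimator assumes link weights are shaped by local clusterings:
homogeneous links inside a neighborhood tend to have similar weights, and a
weight approximately factorizes over the links to a shared center.  For a
candidate pair (x, y) two kinds of local evidence are collected:

* **within-set** — a common neighbor α with x, y ∈ Γ(α).  Under an
  independence (product) hypothesis w_xy ≈ w_αx · w_αy; the residual
  correction is the average of the observed ratios w_ij / (w_αi · w_αj)
  over the links (i, j) already present inside Γ(α), with add-one
  smoothing so an empty neighborhood yields the pure product:

      R_α = (1 + Σ_{(i,j)⊆Γ(α)} w_ij / (w_αi·w_αj)) / (1 + m_α),
      estimate_α = w_αx · w_αy · R_α,

  weighted by the link density inside Γ(α) (the local clustering
  coefficient of α) as connection probability.

* **cross-set** — a pair of centers α ∈ Γ(x), β ∈ Γ(y), α ≠ β.  The same
  product logic runs across the two neighborhoods using the links spanning
  Γ(α) and Γ(β), weighted by the cross-neighborhood link density.

The final prediction is the evidence estimates combined under their
probabilities normalized to sum to one; with no evidence (or all-zero
probabilities) the prediction is 0, matching the convention that a
non-observed link has weight zero.

The candidate pair itself is excluded from every ratio and density, so
predicting the hidden weight of a *known* link cannot leak the target
through the counts.

All evidence sums run in lexicographic node order, making predictions
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .graph import Node, Pair, label_key, pair_key, validate_graph

__all__ = [
    "WithinSetEvidence",
    "CrossSetEvidence",
    "WeightPrediction",
    "NeighborSetPredictor",
    "within_ratio",
    "within_estimate",
    "within_probability",
    "cross_ratio",
    "cross_probability",
    "predict_weight",
    "predict_weights",
]


@dataclass(frozen=True)
class WithinSetEvidence:
    """Evidence from a single common neighbor α of the candidate pair."""

    center: Node
    estimate: float
    probability: float


@dataclass(frozen=True)
class CrossSetEvidence:
    """Evidence from a pair of centers α ∈ Γ(x), β ∈ Γ(y)."""

    centers: tuple
    estimate: float
    probability: float


@dataclass(frozen=True)
class WeightPrediction:
    pair: Pair
    predicted_weight: float
    evidence: tuple
    normalized_probabilities: tuple

    def to_dict(self) -> dict:
        return {
            "pair": [str(self.pair[0]), str(self.pair[1])],
            "predicted_weight": self.predicted_weight,
            "evidence": [
                {
                    "kind": "within" if isinstance(ev, WithinSetEvidence) else "cross",
                    "centers": [str(ev.center)] if isinstance(ev, WithinSetEvidence) else [str(c) for c in ev.centers],
                    "estimate": ev.estimate,
                    "probability": ev.probability,
                    "normalized_probability": p,
                }
                for ev, p in zip(self.evidence, self.normalized_probabilities)
            ],
        }


class NeighborSetPredictor:
    """Weight predictor over a fixed training graph with memoized evidence.

    Per-center internal-link terms and per-center-pair cross terms are
    computed once and reused across candidate pairs; exclusion of the
    candidate pair is applied at summation time, so caching cannot change
    any result.
    """

    def __init__(self, G: nx.Graph):
        validate_graph(G)
        self._G = G
        # adjacency as plain dicts with deterministically sorted neighbor lists
        self._w = {v: {u: G[v][u]["weight"] for u in G[v]} for v in G}
        self._nbrs = {v: tuple(sorted(G[v], key=label_key)) for v in G}
        self._within_cache: dict = {}
        self._cross_cache: dict = {}

    # -- within-set quantities -------------------------------------------

    def _within_terms(self, alpha: Node):
        """Sorted [(edge-key, ratio term)] for links inside Γ(α)."""
        cached = self._within_cache.get(alpha)
        if cached is None:
            nbrs = self._nbrs[alpha]
            w_a = self._w[alpha]
            terms = []
            for i, u in enumerate(nbrs):
                w_u = self._w[u]
                for v in nbrs[i + 1 :]:
                    wuv = w_u.get(v)
                    if wuv is not None:
                        terms.append((pair_key(u, v), wuv / (w_a[u] * w_a[v])))
            cached = tuple(terms)
            self._within_cache[alpha] = cached
        return cached

    def within_ratio(self, alpha: Node, exclude: Pair | None = None) -> float:
        """Smoothed average clustering-weight ratio inside Γ(α)."""
        key = pair_key(*exclude) if exclude is not None else None
        total, m = 0.0, 0
        for ekey, term in self._within_terms(alpha):
            if ekey == key:
                continue
            total += term
            m += 1
        return (1.0 + total) / (1.0 + m)

    def within_estimate(self, alpha: Node, x: Node, y: Node) -> float:
        w_a = self._w[alpha]
        if x not in w_a or y not in w_a:
            raise ValueError(f"{x!r} and {y!r} must both be adjacent to center {alpha!r}")
        return w_a[x] * w_a[y] * self.within_ratio(alpha, (x, y))

    def within_probability(self, alpha: Node, exclude: Pair | None = None) -> float:
        """Link density inside Γ(α): the local clustering coefficient."""
        k = len(self._nbrs[alpha])
        if k < 2:
            return 0.0
        key = pair_key(*exclude) if exclude is not None else None
        m = sum(1 for ekey, _ in self._within_terms(alpha) if ekey != key)
        return m / (k * (k - 1) / 2)

    # -- cross-set quantities --------------------------------------------

    def _cross_terms(self, alpha: Node, beta: Node):
        """Sorted cross-link terms between Γ(α) and Γ(β).

        Returns (terms, n_pairs) where terms is a tuple of
        (edge-key, ratio term) over existing links spanning the two
        neighborhoods and n_pairs the number of distinct unordered pairs
        {u, v}, u ∈ Γ(α), v ∈ Γ(β), u ≠ v.  A link valid in both
        orientations contributes the mean of its two orientation ratios,
        once.
        """
        a, b = (alpha, beta) if label_key(alpha) <= label_key(beta) else (beta, alpha)
        cached = self._cross_cache.get((a, b))
        if cached is None:
            ga, gb = set(self._nbrs[a]), set(self._nbrs[b])
            w_a, w_b = self._w[a], self._w[b]
            links = set()
            for u in ga:
                w_u = self._w[u]
                for v in gb:
                    if u != v and v in w_u:
                        links.add(pair_key(u, v))
            terms = []
            for ekey in sorted(links, key=lambda p: (label_key(p[0]), label_key(p[1]))):
                u, v = ekey
                wuv = self._w[u][v]
                parts = []
                if u in ga and v in gb:
                    parts.append(wuv / (w_a[u] * w_b[v]))
                if v in ga and u in gb:
                    parts.append(wuv / (w_a[v] * w_b[u]))
                terms.append((ekey, sum(parts) / len(parts)))
            both = len(ga & gb)
            n_pairs = len(ga) * len(gb) - both - both * (both - 1) // 2
            cached = (tuple(terms), n_pairs)
            self._cross_cache[(a, b)] = cached
        return cached

    def cross_ratio(self, alpha: Node, beta: Node, exclude: Pair | None = None) -> float:
        """Smoothed average weight ratio across Γ(α) and Γ(β)."""
        if alpha == beta:
            raise ValueError("cross-set centers must be distinct")
        key = pair_key(*exclude) if exclude is not None else None
        terms, _ = self._cross_terms(alpha, beta)
        total, m = 0.0, 0
        for ekey, term in terms:
            if ekey == key:
                continue
            total += term
            m += 1
        return (1.0 + total) / (1.0 + m)

    def cross_probability(self, alpha: Node, beta: Node, exclude: Pair | None = None) -> float:
        """Connection density across Γ(α) and Γ(β)."""
        if alpha == beta:
            raise ValueError("cross-set centers must be distinct")
        key = pair_key(*exclude) if exclude is not None else None
        terms, n_pairs = self._cross_terms(alpha, beta)
        if n_pairs == 0:
            return 0.0
        m = sum(1 for ekey, _ in terms if ekey != key)
        return m / n_pairs

    # -- the combined predictor ------------------------------------------

    def predict(self, x: Node, y: Node) -> WeightPrediction:
        """Full evidence-combination prediction for one candidate pair."""
        if x == y:
            raise ValueError("candidate pair must consist of two distinct nodes")
        for v in (x, y):
            if v not in self._w:
                raise KeyError(f"node {v!r} not in graph")
        exclude = pair_key(x, y)
        gx = [v for v in self._nbrs[x] if v != y]
        gy = [v for v in self._nbrs[y] if v != x]
        sx, sy = set(gx), set(gy)
        w_x, w_y = self._w[x], self._w[y]

        evidence: list = []
        for alpha in sorted(sx & sy, key=label_key):
            w_a = self._w[alpha]
            evidence.append(
                WithinSetEvidence(
                    center=alpha,
                    estimate=w_a[x] * w_a[y] * self.within_ratio(alpha, exclude),
                    probability=self.within_probability(alpha, exclude),
                )
            )
        seen: set = set()
        cross_pairs = []
        for alpha in gx:
            for beta in gy:
                if alpha == beta:
                    continue
                key = pair_key(alpha, beta)
                if key not in seen:
                    seen.add(key)
                    cross_pairs.append(key)
        for a, b in sorted(cross_pairs, key=lambda p: (label_key(p[0]), label_key(p[1]))):
            pres = []
            if a in sx and b in sy:
                pres.append(w_x[a] * w_y[b])
            if b in sx and a in sy:
                pres.append(w_x[b] * w_y[a])
            evidence.append(
                CrossSetEvidence(
                    centers=(a, b),
                    estimate=(sum(pres) / len(pres)) * self.cross_ratio(a, b, exclude),
                    probability=self.cross_probability(a, b, exclude),
                )
            )

        total_p = sum(ev.probability for ev in evidence)
        if not evidence or total_p == 0.0:
            return WeightPrediction(exclude, 0.0, tuple(evidence), tuple(0.0 for _ in evidence))
        normed = tuple(ev.probability / total_p for ev in evidence)
        w_hat = sum(p * ev.estimate for ev, p in zip(evidence, normed))
        return WeightPrediction(exclude, w_hat, tuple(evidence), normed)

    def predict_many(self, pairs: Iterable[Pair]) -> list[float]:
        return [self.predict(x, y).predicted_weight for x, y in pairs]


# -- convenience module-level wrappers -----------------------------------


def within_ratio(G: nx.Graph, alpha: Node, exclude: Pair | None = None) -> float:
    return NeighborSetPredictor(G).within_ratio(alpha, exclude)


def within_estimate(G: nx.Graph, alpha: Node, x: Node, y: Node) -> float:
    return NeighborSetPredictor(G).within_estimate(alpha, x, y)


def within_probability(G: nx.Graph, alpha: Node, exclude: Pair | None = None) -> float:
    return NeighborSetPredictor(G).within_probability(alpha, exclude)


def cross_ratio(G: nx.Graph, alpha: Node, beta: Node, exclude: Pair | None = None) -> float:
    return NeighborSetPredictor(G).cross_ratio(alpha, beta, exclude)


def cross_probability(G: nx.Graph, alpha: Node, beta: Node, exclude: Pair | None = None) -> float:
    return NeighborSetPredictor(G).cross_probability(alpha, beta, exclude)


def predict_weight(G: nx.Graph, x: Node, y: Node) -> WeightPrediction:
    return NeighborSetPredictor(G).predict(x, y)


def predict_weights(G: nx.Graph, pairs: Sequence[Pair]) -> list[float]:
    return NeighborSetPredictor(G).predict_many(pairs)
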