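"""Toy fixture and synthetic weighted-network generator.

The generator realizes the modelling assumption behind the neighbor-set
predictor: each node carries a latent affinity a_v, and an edge's weight is
the product of its endpoints' affinities up to multiplicative log-normal
noise, w_uv = a_u·a_v·exp(σ·z_uv).  At σ = 0 weights factorize exactly, so
every weight ratio w_uv·w_xy/(w_ux·w_vy) over shared nodes equals one — the
regime in which the predictor should recover held-out weights almost
perfectly.  Noise is multiplicative (not additive) so weights stay
positive.  Edges are placed by a community block model (p_in/p_out), which
degenerates to an Erdős–Rényi graph when there is a single community.

The generated graph is max-normalized; the hidden truth (affinities and
noiseless weights) is returned alongside for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .graph import label_key, normalize_weights, pair_key

__all__ = ["SyntheticSpec", "SyntheticTruth", "toy_fig1", "generate_multiplicative", "FIG1_WEIGHTS"]

# Frozen weight assignment for the weighted toy fixture (the topology carries
# no numeric weights of its own); arbitrary but fixed so worked examples are
# reproducible.
FIG1_WEIGHTS = {
    ("alpha", "a"): 0.5,
    ("alpha", "b"): 0.4,
    ("alpha", "c"): 0.8,
    ("alpha", "d"): 0.5,
    ("beta", "d"): 0.5,
    ("beta", "e"): 0.5,
    ("beta", "f"): 0.3,
    ("b", "c"): 0.6,
    ("d", "e"): 0.25,
}


def toy_fig1(weighted: bool = False) -> nx.Graph:
    """Two overlapping neighbor sets: the didactic 8-node toy graph.

    Node ``alpha`` is adjacent to {a, b, c, d} (neighbor set A) and node
    ``beta`` to {d, e, f} (neighbor set B); d is their one common neighbor.
    A contains a single internal link (b, c) and a single link (d, e) spans
    A and B, giving within-A density 1/6 and cross density 1/11.
    """
    G = nx.Graph()
    for (u, v), w in FIG1_WEIGHTS.items():
        G.add_edge(u, v, weight=w if weighted else 1.0)
    return G


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the multiplicative-weight block-model generator.

    Defaults are the study conditions used throughout the test harness:
    n = 60 nodes at edge density 0.3 with affinities in [0.2, 1.0] (a 25x
    spread of weights, comparable to normalized empirical networks) and no
    noise; a single community, so the block model is a plain random graph.
    """

    n: int = 60
    edge_density: float = 0.3
    affinity_range: tuple = (0.2, 1.0)
    noise_sd: float = 0.0
    community_count: int = 1
    p_in: Optional[float] = None
    p_out: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.affinity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("affinity_range must lie within (0, 1]")
        if not (0 <= self.edge_density <= 1):
            raise ValueError("edge_density must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.community_count < 1:
            raise ValueError("community_count must be >= 1")
        pin = self.p_in if self.p_in is not None else self.edge_density
        pout = self.p_out if self.p_out is not None else self.edge_density
        if pin < pout:
            raise ValueError("p_in must be >= p_out")


@dataclass(frozen=True)
class SyntheticTruth:
    """Hidden generating state: latent affinities and noiseless products."""

    affinities: dict
    noiseless_weights: dict = field(default_factory=dict)


def generate_multiplicative(spec: SyntheticSpec) -> tuple[nx.Graph, SyntheticTruth]:
    """Draw a weighted graph from the multiplicative affinity model."""
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 0x5E)))
    nodes = [f"n{i:03d}" for i in range(spec.n)]
    lo, hi = spec.affinity_range
    affinities = {v: float(a) for v, a in zip(nodes, rng.uniform(lo, hi, size=spec.n))}
    community = {v: i % spec.community_count for i, v in enumerate(nodes)}
    p_in = spec.p_in if spec.p_in is not None else spec.edge_density
    p_out = spec.p_out if spec.p_out is not None else spec.edge_density

    G = nx.Graph()
    G.add_nodes_from(nodes)
    noiseless = {}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            p = p_in if community[u] == community[v] else p_out
            if rng.random() < p:
                base = affinities[u] * affinities[v]
                # the noise draw happens even at noise_sd = 0 (exp(0) = 1) so a
                # fixed seed yields the same topology at every noise level
                w = base * float(np.exp(spec.noise_sd * rng.standard_normal()))
                G.add_edge(u, v, weight=w)
                noiseless[pair_key(u, v)] = base
    if G.number_of_edges() == 0:
        raise ValueError("synthetic spec produced an empty edge set")
    return normalize_weights(G), SyntheticTruth(affinities=affinities, noiseless_weights=noiseless)
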