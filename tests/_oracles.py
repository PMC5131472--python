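"""Independent brute-force reference implementations used only by tests.

These follow the written definitions directly with naive loops and no
caching, deliberately sharing no code with the package's engine, so they
can serve as oracles for equivalence tests.
"""

from __future__ import annotations

import math

import networkx as nx

from netweights.graph import label_key, pair_key


def oracle_score_pair(G: nx.Graph, index: str, x, y) -> float:
    """Triple-loop similarity score straight from the index definitions."""

    def w(u, v):
        return G[u][v]["weight"]

    def strength(z):
        return sum(w(z, u) for u in sorted(G[z], key=label_key))

    total = 0.0
    for z in sorted(G.nodes(), key=label_key):
        if z in (x, y) or not (G.has_edge(x, z) and G.has_edge(z, y)):
            continue
        k = G.degree(z)
        if index == "CN":
            total += 1.0
        elif index == "AA":
            total += 1.0 / math.log(k)
        elif index == "RA":
            total += 1.0 / k
        elif index == "WCN":
            total += (w(x, z) + w(z, y)) / 2.0
        elif index == "WAA":
            total += (w(x, z) + w(z, y)) / (2.0 * math.log(1.0 + strength(z)))
        elif index == "WRA":
            total += (w(x, z) + w(z, y)) / (2.0 * strength(z))
        elif index == "rWCN":
            total += w(x, z) * w(z, y)
        elif index == "rWAA":
            total += w(x, z) * w(z, y) / math.log(1.0 + strength(z))
        elif index == "rWRA":
            total += w(x, z) * w(z, y) / strength(z)
        else:
            raise ValueError(index)
    return total


def oracle_predict_weight(G: nx.Graph, x, y) -> float:
    """Direct-definition neighbor-set weight prediction.

    Enumerates every within-set center and every cross-set center pair from
    the definitions: smoothed ratio averages, neighborhood link densities,
    probability normalization, candidate-pair exclusion.
    """

    def w(u, v):
        return G[u][v]["weight"]

    exclude = pair_key(x, y)

    def within_links(alpha):
        nbrs = sorted(G[alpha], key=label_key)
        out = []
        for i, u in enumerate(nbrs):
            for v in nbrs[i + 1 :]:
                if G.has_edge(u, v) and pair_key(u, v) != exclude:
                    out.append((u, v))
        return out

    gx = sorted((set(G[x]) - {y}), key=label_key)
    gy = sorted((set(G[y]) - {x}), key=label_key)
    evidence = []  # (estimate, probability) in deterministic order

    for alpha in sorted(set(gx) & set(gy), key=label_key):
        links = within_links(alpha)
        total = 0.0
        for u, v in links:
            total += w(u, v) / (w(alpha, u) * w(alpha, v))
        ratio = (1.0 + total) / (1.0 + len(links))
        estimate = w(alpha, x) * w(alpha, y) * ratio
        k = G.degree(alpha)
        prob = len(links) / (k * (k - 1) / 2) if k >= 2 else 0.0
        evidence.append((estimate, prob))

    pairs = sorted(
        {pair_key(a, b) for a in gx for b in gy if a != b},
        key=lambda p: (label_key(p[0]), label_key(p[1])),
    )
    for a, b in pairs:
        ga, gb = set(G[a]), set(G[b])
        links = sorted(
            {
                pair_key(u, v)
                for u in ga
                for v in gb
                if u != v and G.has_edge(u, v) and pair_key(u, v) != exclude
            },
            key=lambda p: (label_key(p[0]), label_key(p[1])),
        )
        total = 0.0
        for u, v in links:  # (u, v) is the canonical order of the link
            parts = []
            if u in ga and v in gb:
                parts.append(w(u, v) / (w(a, u) * w(b, v)))
            if v in ga and u in gb:
                parts.append(w(u, v) / (w(a, v) * w(b, u)))
            total += sum(parts) / len(parts)
        ratio = (1.0 + total) / (1.0 + len(links))
        both = len(ga & gb)
        n_pairs = len(ga) * len(gb) - both - both * (both - 1) // 2
        if n_pairs == 0:
            prob = 0.0
        else:
            prob = len(links) / n_pairs
        pres = []
        if a in set(gx) and b in set(gy):
            pres.append(w(x, a) * w(y, b))
        if b in set(gx) and a in set(gy):
            pres.append(w(x, b) * w(y, a))
        evidence.append(((sum(pres) / len(pres)) * ratio, prob))

    total_p = sum(p for _, p in evidence)
    if not evidence or total_p == 0.0:
        return 0.0
    return sum((p / total_p) * est for est, p in evidence)
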