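"""Readers and writers for edge-list TSV and Pajek .net files.

Both dialects describe an undirected weighted graph.  Input validation is
strict: malformed lines, conflicting duplicate edges, self-loops and
non-positive weights all raise :class:`GraphFormatError` (zero is the
sentinel for a non-observed link downstream, so a zero-weight input edge is
an error, never silently dropped).
"""

from __future__ import annotations

import shlex
from pathlib import Path
from typing import Union

import networkx as nx

from .graph import label_key

__all__ = ["GraphFormatError", "read_edge_list", "write_edge_list", "read_pajek", "write_pajek"]

PathLike = Union[str, Path]


class GraphFormatError(ValueError):
    """Raised for malformed or inconsistent graph files."""


def _add_edge(G: nx.Graph, u, v, w: float, where: str) -> None:
    if u == v:
        raise GraphFormatError(f"{where}: self-loop at node {u!r}")
    if not (w > 0):
        raise GraphFormatError(f"{where}: non-positive weight {w} for edge ({u!r}, {v!r})")
    if G.has_edge(u, v):
        old = G[u][v]["weight"]
        if old != w:
            raise GraphFormatError(
                f"{where}: duplicate edge ({u!r}, {v!r}) with conflicting weights {old} and {w}"
            )
        return
    G.add_edge(u, v, weight=w)


def read_edge_list(path: PathLike, delimiter: str = "\t") -> nx.Graph:
    """Read a "u <delim> v <delim> w" edge list into a weighted graph.

    Lines starting with ``#`` and blank lines are ignored.  Duplicate
    (u, v)/(v, u) lines with equal weight collapse to one edge; a duplicate
    with a conflicting weight is an error.
    """
    G = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            u, v, wtext = (p.strip() for p in parts)
            try:
                w = float(wtext)
            except ValueError:
                raise GraphFormatError(f"{path}:{lineno}: weight {wtext!r} is not a number") from None
            _add_edge(G, u, v, w, where=f"{path}:{lineno}")
    return G


def write_edge_list(G: nx.Graph, path: PathLike, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(
            (tuple(sorted(e, key=label_key)) for e in G.edges()),
            key=lambda e: (label_key(e[0]), label_key(e[1])),
        ):
            fh.write(f"{u}{delimiter}{v}{delimiter}{G[u][v]['weight']!r}\n")


def read_pajek(path: PathLike, arcs: str = "sum") -> nx.Graph:
    """Read a Pajek .net file (*Vertices / *Edges / *Arcs) as undirected.

    ``*Arcs`` entries are symmetrized: when both directions of a pair
    appear, their weights are combined by ``arcs`` ("sum", the default,
    suits flight-count networks where total traffic is the natural
    undirected weight; "max" and "mean" are available).
    """
    if arcs not in ("sum", "max", "mean"):
        raise ValueError(f"unknown arcs policy {arcs!r}")
    labels: dict[int, object] = {}
    n_vertices = 0
    section = None
    arc_weights: dict[tuple, list[float]] = {}
    edge_triples: list[tuple] = []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise GraphFormatError(f"{path}:{lineno}: malformed *Vertices header")
                n_vertices = int(parts[1])
                section = "vertices"
                continue
            if low.startswith("*edges"):
                section = "edges"
                continue
            if low.startswith("*arcs"):
                section = "arcs"
                continue
            if section is None:
                raise GraphFormatError(f"{path}:{lineno}: data before *Vertices header")
            if section == "vertices":
                parts = shlex.split(line)
                if not parts[0].isdigit():
                    raise GraphFormatError(f"{path}:{lineno}: bad vertex index {parts[0]!r}")
                idx = int(parts[0])
                if not (1 <= idx <= n_vertices):
                    raise GraphFormatError(f"{path}:{lineno}: vertex index {idx} out of range")
                labels[idx] = parts[1] if len(parts) > 1 else str(idx)
                continue
            parts = line.split()
            if len(parts) < 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 'i j w' triple")
            try:
                i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise GraphFormatError(f"{path}:{lineno}: malformed triple {line!r}") from None
            for idx in (i, j):
                if not (1 <= idx <= n_vertices):
                    raise GraphFormatError(f"{path}:{lineno}: vertex index {idx} out of range")
            if section == "edges":
                edge_triples.append((i, j, w, lineno))
            else:
                arc_weights.setdefault((min(i, j), max(i, j)), []).append(w)

    if n_vertices == 0 and (edge_triples or arc_weights):
        raise GraphFormatError(f"{path}: missing *Vertices header")

    G = nx.Graph()
    for idx in range(1, n_vertices + 1):
        G.add_node(labels.get(idx, str(idx)))
    for i, j, w, lineno in edge_triples:
        _add_edge(G, labels.get(i, str(i)), labels.get(j, str(j)), w, where=f"{path}:{lineno}")
    combine = {"sum": sum, "max": max, "mean": lambda ws: sum(ws) / len(ws)}[arcs]
    for (i, j), ws in sorted(arc_weights.items()):
        _add_edge(G, labels.get(i, str(i)), labels.get(j, str(j)), combine(ws), where=f"{path}:*Arcs")
    return G


def write_pajek(G: nx.Graph, path: PathLike) -> None:
    nodes = sorted(G.nodes(), key=label_key)
    index = {v: i + 1 for i, v in enumerate(nodes)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for v in nodes:
            fh.write(f'{index[v]} "{v}"\n')
        fh.write("*Edges\n")
        for u, v in sorted(
            (tuple(sorted(e, key=label_key)) for e in G.edges()),
            key=lambda e: (label_key(e[0]), label_key(e[1])),
        ):
            fh.write(f"{index[u]} {index[v]} {G[u][v]['weight']!r}\n")
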