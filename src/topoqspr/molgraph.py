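"""Hydrogen-suppressed molecular graphs and their degree-pair edge partitions.

A molecule is modelled as a simple, finite, connected graph: vertices are
the heavy (non-hydrogen) atoms, edges are bonds with multiplicity collapsed
to one. Every degree-based topological index in :mod:`topoqspr.indices`
depends only on the multiset of endpoint-degree pairs over the edges, so the
central derived object here is the *edge partition*: the count of edges
whose endpoints have degrees ``(m, n)``, stored unordered with ``m <= n``.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx

__all__ = [
    "GraphFormatError",
    "GraphValidationError",
    "MolecularGraph",
    "EdgePartition",
    "read_edge_list",
    "degrees",
    "edge_partition",
]


class GraphFormatError(ValueError):
    """A graph input file is syntactically malformed (self-loop, duplicate edge, bad line)."""


class GraphValidationError(ValueError):
    """A structurally parsed graph violates the molecular-graph invariants."""


class MolecularGraph:
    """A simple, connected, undirected graph of heavy atoms.

    Vertex identifiers are opaque tokens (any hashable; files yield strings).
    Construction validates the invariants: no self-loops, no duplicate
    edges, at least one edge, and a single connected component.

    Parameters
    ----------
    edges
        Iterable of 2-tuples of vertex tokens.
    name
        Optional molecule name carried through to tabular output.
    """

    def __init__(self, edges: Iterable[tuple], name: str | None = None):
        g = nx.Graph()
        for e in edges:
            u, v = e
            if u == v:
                raise GraphValidationError(f"self-loop on vertex {u!r}")
            if g.has_edge(u, v):
                raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v)
        if g.number_of_edges() == 0:
            raise GraphValidationError("graph has no edges")
        if not nx.is_connected(g):
            sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
            raise GraphValidationError(
                f"graph is disconnected: {len(sizes)} components of sizes {sizes}"
            )
        self._g = g
        self.name = name

    @property
    def nx_graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._g

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._g.edges)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v) -> int:
        return self._g.degree[v]

    def relabeled(self, mapping: Mapping) -> "MolecularGraph":
        """Return a copy with vertices renamed through ``mapping`` (must be injective)."""
        return MolecularGraph(
            ((mapping[u], mapping[v]) for u, v in self._g.edges), name=self.name
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = f" {self.name!r}" if self.name else ""
        return f"<MolecularGraph{label}: {self.n_vertices} vertices, {self.n_edges} edges>"


class EdgePartition:
    """Counts of edges per unordered endpoint-degree pair.

    ``counts`` maps ``(m, n)`` with ``1 <= m <= n`` to a positive edge count.
    Keys given as ``(n, m)`` are canonicalised. When derived from a graph the
    counts sum to the number of edges.
    """

    def __init__(self, counts: Mapping[tuple[int, int], int]):
        canon: Counter = Counter()
        for (m, n), c in counts.items():
            m, n = int(m), int(n)
            c = int(c)
            if m < 1 or n < 1:
                raise ValueError(f"degrees must be >= 1, got ({m}, {n})")
            if c <= 0:
                raise ValueError(f"edge count for ({m}, {n}) must be positive, got {c}")
            canon[(min(m, n), max(m, n))] += c
        self._counts: dict[tuple[int, int], int] = dict(sorted(canon.items()))

    @property
    def counts(self) -> dict[tuple[int, int], int]:
        return dict(self._counts)

    @property
    def total(self) -> int:
        """Total number of edges across all degree classes."""
        return sum(self._counts.values())

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return len(self._counts)

    def __getitem__(self, pair: tuple[int, int]) -> int:
        m, n = pair
        return self._counts[(min(m, n), max(m, n))]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgePartition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"({m},{n}): {c}" for (m, n), c in self._counts.items())
        return f"EdgePartition({{{body}}})"


def read_edge_list(path: str | Path, name: str | None = None) -> MolecularGraph:
    """Read one molecular graph from a plain-text edge list.

    Format: UTF-8, one edge per line as two whitespace-separated vertex
    tokens; blank lines and lines starting with ``#`` are ignored.

    Raises
    ------
    GraphFormatError
        On a malformed line, self-loop or duplicate edge (the message names
        the offending line number).
    GraphValidationError
        If the file is empty of edges or the graph is disconnected.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two vertex tokens, got {len(tokens)}"
                )
            u, v = tokens
            if u == v:
                raise GraphFormatError(f"{path}:{lineno}: self-loop on vertex {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise GraphFormatError(f"{path}:{lineno}: duplicate edge {u!r}-{v!r}")
            seen.add(key)
            edges.append((u, v))
    if not edges:
        raise GraphValidationError(f"{path}: no edges found")
    return MolecularGraph(edges, name=name if name is not None else path.stem)


def degrees(g: MolecularGraph) -> dict:
    """Map each vertex to its degree (number of adjacent vertices)."""
    return dict(g.nx_graph.degree)


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Tally every edge by the unordered degrees of its endpoints."""
    deg = g.nx_graph.degree
    counts: Counter = Counter()
    for u, v in g.nx_graph.edges:
        du, dv = deg[u], deg[v]
        counts[(min(du, dv), max(du, dv))] += 1
    return EdgePartition(counts)
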