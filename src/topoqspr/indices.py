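"""Nine degree-based topological indices evaluated from edge partitions.

Each index is a sum over the edges ``uv`` of a symmetric function of the
endpoint degrees ``(d_u, d_v)``; on an edge partition this collapses to a
partition-weighted sum. Canonical column order everywhere is::

    ABC, RA, S, GA, M1, M2, H, HM, F

i.e. atom-bond connectivity, Randić, sum-connectivity, geometric-arithmetic,
first/second Zagreb, harmonic, hyper-Zagreb and forgotten indices. M1, M2,
HM and F are integers whenever the degrees are; the others are irrational
in general and are kept at full floating precision — rounding is a
presentation concern only (see :func:`round_half_up`).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, NamedTuple

from .molgraph import EdgePartition, MolecularGraph

__all__ = [
    "INDEX_NAMES",
    "IndexVector",
    "UnknownIndexError",
    "compute_index",
    "compute_all",
    "compute_from_graph",
    "round_half_up",
]

#: Canonical index order used in all tabular output.
INDEX_NAMES: tuple[str, ...] = ("ABC", "RA", "S", "GA", "M1", "M2", "H", "HM", "F")

# Per-edge term t(m, n) of each index; all symmetric in (m, n).
_TERMS: dict[str, Callable[[int, int], float]] = {
    "ABC": lambda m, n: math.sqrt((m + n - 2) / (m * n)),
    "RA": lambda m, n: 1.0 / math.sqrt(m * n),
    "S": lambda m, n: 1.0 / math.sqrt(m + n),
    "GA": lambda m, n: 2.0 * math.sqrt(m * n) / (m + n),
    "M1": lambda m, n: m + n,
    "M2": lambda m, n: m * n,
    "H": lambda m, n: 2.0 / (m + n),
    "HM": lambda m, n: (m + n) ** 2,
    "F": lambda m, n: m * m + n * n,
}


class UnknownIndexError(ValueError):
    """Raised for an index identifier outside the nine supported names."""


class IndexVector(NamedTuple):
    """The nine topological index values for one molecule, in canonical order."""

    abc: float
    ra: float
    s: float
    ga: float
    m1: float
    m2: float
    h: float
    hm: float
    f: float

    def to_dict(self) -> dict[str, float]:
        """Values keyed by canonical index name (``ABC`` ... ``F``)."""
        return dict(zip(INDEX_NAMES, self))

    def rounded(self, digits: int = 2) -> "IndexVector":
        """Presentation copy with every component rounded half-up."""
        return IndexVector(*(round_half_up(v, digits) for v in self))


def _canonical_name(name: str) -> str:
    key = str(name).strip().upper()
    if key not in _TERMS:
        raise UnknownIndexError(
            f"unknown index {name!r}; expected one of {', '.join(INDEX_NAMES)}"
        )
    return key


def compute_index(p: EdgePartition, name: str) -> float:
    """Evaluate one named index as a partition-weighted sum.

    Returns ``sum over classes (m, n) of count * t(m, n)`` with ``t`` the
    per-edge term of the named index. Integer-valued indices (M1, M2, HM, F)
    come back as Python ints.
    """
    key = _canonical_name(name)
    if len(p) == 0:
        raise ValueError("empty edge partition")
    term = _TERMS[key]
    return sum(c * term(m, n) for (m, n), c in p.items())


def compute_all(p: EdgePartition) -> IndexVector:
    """All nine indices of one partition, in canonical order."""
    return IndexVector(*(compute_index(p, name) for name in INDEX_NAMES))


def compute_from_graph(g: MolecularGraph, name: str) -> float:
    """Evaluate one index by summing directly over the edges of ``g``.

    Deliberately bypasses the edge partition: this is the independent
    computation path used to cross-check :func:`compute_index`.
    """
    key = _canonical_name(name)
    term = _TERMS[key]
    deg = g.nx_graph.degree
    return sum(term(deg[u], deg[v]) for u, v in g.nx_graph.edges)


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero (half-up), e.g. 15.665 -> 15.67 at 2 dp.

    Plain :func:`round` is banker's rounding; printed chemistry tables use
    half-up, so presentation output goes through this helper.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
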