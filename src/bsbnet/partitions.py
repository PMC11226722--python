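"""Degree-based vertex and edge partitions of the benzyl sulfamoyl network.

The benzyl sulfamoyl network ``BS_b(m, n)`` is a two-parameter molecular
graph family with vertex degrees in ``{1, 2, 3}``, order ``8mn + 2m + 2n``
and size ``12mn``.  Every degree-based topological index of the network is
determined by its *edge partition* — the multiset of unordered endpoint
degree pairs with their multiplicities — so that partition is the central
data structure of this package.

Two vertex-partition variants are provided.  The published class counts
(``as_printed``) fail both the order identity and the handshake lemma
against the (self-consistent) edge partition; the ``consistent`` variant,
derived by incidence counting from the edge partition, satisfies both and
is the default everywhere downstream.

All counts are exact integers; polynomial class counts are evaluated in
integer arithmetic, never floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

__all__ = [
    "GridParams",
    "VertexPartition",
    "EdgePartition",
    "ConsistencyReport",
    "bsb_order_size",
    "bsb_vertex_partition",
    "bsb_edge_partition",
    "validate",
    "partition_from_edges",
    "read_edge_list",
    "partitions_to_json",
]


@dataclass(frozen=True)
class GridParams:
    """Grid parameters ``(m, n)`` selecting a BS_b network; both must be >= 1."""

    m: int
    n: int

    def __post_init__(self) -> None:
        for name, value in (("m", self.m), ("n", self.n)):
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")


@dataclass(frozen=True)
class VertexPartition:
    """Map from vertex degree to vertex count, plus the declared order.

    The declared ``order`` may disagree with the sum of the counts (that is
    exactly what the ``as_printed`` BS_b variant does); :func:`validate`
    reports such inconsistencies instead of raising.
    """

    entries: Mapping[int, int]
    order: int

    @classmethod
    def from_entries(cls, entries: Mapping[int, int]) -> "VertexPartition":
        """Build a partition whose order is the sum of its counts."""
        return cls(entries=dict(entries), order=sum(entries.values()))

    def degree_sum(self) -> int:
        return sum(d * c for d, c in self.entries.items())


@dataclass(frozen=True)
class EdgePartition:
    """Map from canonical (d_u <= d_v) degree pair to edge count, plus size."""

    entries: Mapping[tuple[int, int], int]
    size: int

    @classmethod
    def from_entries(cls, entries: Mapping[tuple[int, int], int]) -> "EdgePartition":
        canon: dict[tuple[int, int], int] = {}
        for (du, dv), count in entries.items():
            key = (du, dv) if du <= dv else (dv, du)
            canon[key] = canon.get(key, 0) + count
        return cls(entries=canon, size=sum(canon.values()))

    def incidences(self, degree: int) -> int:
        """Number of (edge, endpoint-of-that-degree) incidences."""
        total = 0
        for (du, dv), count in self.entries.items():
            total += count * ((du == degree) + (dv == degree))
        return total


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of the handshake/incidence validation of a partition pair."""

    size_ok: bool
    order_ok: bool
    handshake_ok: bool
    incidence_ok: bool
    messages: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return self.size_ok and self.order_ok and self.handshake_ok and self.incidence_ok


def bsb_order_size(params: GridParams) -> tuple[int, int]:
    """Order ``8mn + 2m + 2n`` and size ``12mn`` of BS_b(m, n)."""
    m, n = params.m, params.n
    return 8 * m * n + 2 * m + 2 * n, 12 * m * n


def bsb_edge_partition(params: GridParams) -> EdgePartition:
    """Edge partition of BS_b(m, n) by unordered endpoint degree pairs.

    Classes: ``(1,3) -> 2m + 2n + 1``, ``(2,3) -> 4(m + n - 1)``,
    ``(3,3) -> 12mn - 6(m + n) + 3``.  The counts sum to ``12mn`` for all
    ``m, n >= 1``.
    """
    m, n = params.m, params.n
    entries = {
        (1, 3): 2 * m + 2 * n + 1,
        (2, 3): 4 * (m + n - 1),
        (3, 3): 12 * m * n - 6 * (m + n) + 3,
    }
    return EdgePartition(entries=entries, size=12 * m * n)


def bsb_vertex_partition(params: GridParams, mode: str = "consistent") -> VertexPartition:
    """Vertex partition of BS_b(m, n).

    Parameters
    ----------
    mode
        ``"consistent"`` (default): counts derived by incidence counting
        from the edge partition; they satisfy the order identity
        ``sum = 8mn + 2m + 2n`` and the handshake lemma
        ``sum d*count(d) = 24mn``.
        ``"as_printed"``: the published class counts, kept for fidelity;
        they sum to ``2mn + 2m + 2n + 2`` and fail the handshake lemma.
    """
    m, n = params.m, params.n
    order, _ = bsb_order_size(params)
    if mode == "consistent":
        entries = {
            1: 2 * m + 2 * n + 1,
            2: 2 * (m + n - 1),
            3: 8 * m * n - 2 * (m + n) + 1,
        }
    elif mode == "as_printed":
        entries = {
            1: 2 * m + 2 * n + 1,
            2: 2 * (m + n) - 1,
            3: 2 * m * n - 2 * (m + n - 1),
        }
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'consistent' or 'as_printed'")
    return VertexPartition(entries=entries, order=order)


def validate(vp: VertexPartition, ep: EdgePartition) -> ConsistencyReport:
    """Check a vertex/edge partition pair for mutual consistency.

    Four checks are performed; failures are reported, never raised:

    * ``size_ok`` — edge counts sum to the declared size;
    * ``order_ok`` — vertex counts sum to the declared order;
    * ``handshake_ok`` — handshake lemma, ``sum d*count(d) == 2*size``;
    * ``incidence_ok`` — per degree ``d``, the number of edge-endpoint
      incidences of degree ``d`` equals ``d * count(d)``.
    """
    messages: list[str] = []

    size_ok = sum(ep.entries.values()) == ep.size
    if not size_ok:
        messages.append(
            f"edge counts sum to {sum(ep.entries.values())}, declared size is {ep.size}"
        )

    order_ok = sum(vp.entries.values()) == vp.order
    if not order_ok:
        messages.append(
            f"vertex counts sum to {sum(vp.entries.values())}, declared order is {vp.order}"
        )

    degree_sum = vp.degree_sum()
    handshake_ok = degree_sum == 2 * ep.size
    if not handshake_ok:
        messages.append(
            f"handshake lemma fails: sum of degrees {degree_sum} != 2*size = {2 * ep.size}"
        )

    incidence_ok = True
    degrees = set(vp.entries) | {d for pair in ep.entries for d in pair}
    for d in sorted(degrees):
        expected = d * vp.entries.get(d, 0)
        actual = ep.incidences(d)
        if actual != expected:
            incidence_ok = False
            messages.append(
                f"incidence mismatch for degree {d}: edge classes give {actual}, "
                f"vertex partition implies {expected}"
            )

    return ConsistencyReport(
        size_ok=size_ok,
        order_ok=order_ok,
        handshake_ok=handshake_ok,
        incidence_ok=incidence_ok,
        messages=tuple(messages),
    )


def partition_from_edges(
    edges: Iterable[tuple[str, str]],
) -> tuple[VertexPartition, EdgePartition]:
    """Degree partitions of an explicit simple undirected graph.

    Vertex identifiers are opaque; self-loops and duplicate edges (in either
    orientation) are rejected.  The returned pair always passes
    :func:`validate`.
    """
    seen: set[tuple[str, str]] = set()
    degree: dict[str, int] = {}
    edge_list: list[tuple[str, str]] = []
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop at vertex {u!r} is not allowed")
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            raise ValueError(f"duplicate edge {key!r}")
        seen.add(key)
        edge_list.append((u, v))
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1

    vp_entries: dict[int, int] = {}
    for d in degree.values():
        vp_entries[d] = vp_entries.get(d, 0) + 1

    ep_entries: dict[tuple[int, int], int] = {}
    for u, v in edge_list:
        du, dv = degree[u], degree[v]
        key = (du, dv) if du <= dv else (dv, du)
        ep_entries[key] = ep_entries.get(key, 0) + 1

    return (
        VertexPartition.from_entries(vp_entries),
        EdgePartition.from_entries(ep_entries),
    )


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a plain-text edge list: one edge per line, two whitespace-separated
    vertex tokens; lines starting with ``#`` and blank lines are ignored."""
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"{path}:{lineno}: expected two vertex tokens, got {line!r}")
        edges.append((tokens[0], tokens[1]))
    return edges


def partitions_to_json(vp: VertexPartition, ep: EdgePartition) -> str:
    """Serialize a partition pair to the package's JSON interchange format."""
    payload = {
        "vertex_partition": {str(d): c for d, c in sorted(vp.entries.items())},
        "edge_partition": [
            {"du": du, "dv": dv, "count": c}
            for (du, dv), c in sorted(ep.entries.items())
        ],
        "order": vp.order,
        "size": ep.size,
    }
    return json.dumps(payload, indent=2)
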