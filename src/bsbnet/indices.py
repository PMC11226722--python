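"""Degree-based topological index engine.

Every index here has the form ``sum over edges of f(d_u, d_v)`` for a
symmetric per-edge contribution ``f``; on an edge partition the sum
collapses to a weighted sum over degree classes, which is what
:func:`edge_sum` computes.  The Balaban index additionally needs the
graph's order and size for its global prefactor, carried by
:class:`BalabanContext`.

Contributions returning integers are summed in exact integer arithmetic
(``M1``, ``M2``, ``HM``, ``F``, ``ReZG3``); irrational contributions are
evaluated at full floating precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

from .partitions import EdgePartition

__all__ = [
    "ContributionRule",
    "BalabanContext",
    "IndexValue",
    "CATALOG",
    "edge_sum",
    "randic",
    "abc",
    "ga",
    "zagreb1",
    "zagreb2",
    "hyper_zagreb",
    "forgotten",
    "rezg1",
    "rezg2",
    "rezg3",
    "balaban",
    "balaban_inner_sum",
    "compute_all",
    "DEFAULT_ALPHAS",
]


@dataclass(frozen=True)
class ContributionRule:
    """A named symmetric per-edge contribution ``(d_u, d_v) -> value``."""

    name: str
    contribution: Callable[[int, int], float]
    needs_graph_context: bool = False

    def __call__(self, du: int, dv: int) -> float:
        return self.contribution(du, dv)


@dataclass(frozen=True)
class BalabanContext:
    """Order and size of the underlying graph, for the Balaban prefactor."""

    order: int
    size: int

    @property
    def prefactor(self) -> float:
        """``size / (size - order + 2)`` — the convention that reproduces the
        published BS_b values (the denominator is the cyclomatic number + 1)."""
        den = self.size - self.order + 2
        if den <= 0:
            raise ValueError(
                f"Balaban prefactor undefined: size - order + 2 = {den} <= 0"
            )
        return self.size / den


@dataclass(frozen=True)
class IndexValue:
    """A computed index value together with what it was computed on."""

    name: str
    value: float
    params: object = None


def _check_degrees(du: int, dv: int) -> None:
    if du <= 0 or dv <= 0:
        raise ValueError(f"degrees must be positive, got ({du}, {dv})")


def _abc(du: int, dv: int) -> float:
    _check_degrees(du, dv)
    return math.sqrt((du + dv - 2) / (du * dv))


def _ga(du: int, dv: int) -> float:
    _check_degrees(du, dv)
    return 2.0 * math.sqrt(du * dv) / (du + dv)


def _rezg1(du: int, dv: int) -> float:
    _check_degrees(du, dv)
    return (du + dv) / (du * dv)


CATALOG: Mapping[str, ContributionRule] = {
    "M1": ContributionRule("M1", lambda a, b: a + b),
    "M2": ContributionRule("M2", lambda a, b: a * b),
    "ABC": ContributionRule("ABC", _abc),
    "GA": ContributionRule("GA", _ga),
    "HM": ContributionRule("HM", lambda a, b: (a + b) ** 2),
    "F": ContributionRule("F", lambda a, b: a * a + b * b),
    "ReZG1": ContributionRule("ReZG1", _rezg1),
    "ReZG2": ContributionRule("ReZG2", lambda a, b: (a * b) / (a + b)),
    "ReZG3": ContributionRule("ReZG3", lambda a, b: (a * b) * (a + b)),
    "J": ContributionRule("J", lambda a, b: 1.0 / math.sqrt(a * b), needs_graph_context=True),
}

#: Randić exponents reported alongside the named catalog; alpha = 1 is omitted
#: because R_1 coincides with the second Zagreb index M2.
DEFAULT_ALPHAS: tuple[float, ...] = (-1.0, 0.5, -0.5)


def edge_sum(ep: EdgePartition, rule: ContributionRule) -> float:
    """Weighted sum of ``rule`` over the degree classes of ``ep``."""
    if rule.needs_graph_context:
        raise ValueError(
            f"rule {rule.name!r} needs graph context; use balaban() instead"
        )
    return sum(count * rule(du, dv) for (du, dv), count in ep.entries.items())


def randic(ep: EdgePartition, alpha: float) -> float:
    """Generalized Randić index ``sum count * (d_u * d_v)^alpha``.

    ``alpha`` is an arbitrary real; ``alpha = 1`` equals M2, ``alpha = -1/2``
    equals the Balaban inner sum, ``alpha = 0`` returns the size.
    """
    total = 0.0
    exact = float(alpha).is_integer() and alpha >= 0
    if exact:
        return sum(
            count * (du * dv) ** int(alpha) for (du, dv), count in ep.entries.items()
        )
    for (du, dv), count in ep.entries.items():
        _check_degrees(du, dv)
        total += count * float(du * dv) ** alpha
    return total


def abc(ep: EdgePartition) -> float:
    """Atom-bond connectivity index."""
    return edge_sum(ep, CATALOG["ABC"])


def ga(ep: EdgePartition) -> float:
    """Geometric-arithmetic index; every per-edge term is <= 1."""
    return edge_sum(ep, CATALOG["GA"])


def zagreb1(ep: EdgePartition) -> float:
    """First Zagreb index M1."""
    return edge_sum(ep, CATALOG["M1"])


def zagreb2(ep: EdgePartition) -> float:
    """Second Zagreb index M2."""
    return edge_sum(ep, CATALOG["M2"])


def hyper_zagreb(ep: EdgePartition) -> float:
    """Hyper-Zagreb index HM = sum (d_u + d_v)^2."""
    return edge_sum(ep, CATALOG["HM"])


def forgotten(ep: EdgePartition) -> float:
    """Forgotten index F = sum (d_u^2 + d_v^2)."""
    return edge_sum(ep, CATALOG["F"])


def rezg1(ep: EdgePartition) -> float:
    """First redefined Zagreb index."""
    return edge_sum(ep, CATALOG["ReZG1"])


def rezg2(ep: EdgePartition) -> float:
    """Second redefined Zagreb index."""
    return edge_sum(ep, CATALOG["ReZG2"])


def rezg3(ep: EdgePartition) -> float:
    """Third redefined Zagreb index."""
    return edge_sum(ep, CATALOG["ReZG3"])


def balaban_inner_sum(ep: EdgePartition) -> float:
    """``sum count / sqrt(d_u * d_v)`` — identical to randic(ep, -1/2)."""
    return sum(
        count / math.sqrt(du * dv) for (du, dv), count in ep.entries.items()
    )


def balaban(ep: EdgePartition, ctx: BalabanContext) -> float:
    """Balaban index ``(size/(size-order+2)) * sum count/sqrt(d_u d_v)``.

    Undefined on an empty edge set or when the prefactor denominator
    (cyclomatic number + 1) is non-positive.
    """
    if ep.size == 0:
        raise ValueError("Balaban index undefined for an empty edge set")
    return ctx.prefactor * balaban_inner_sum(ep)


def alpha_key(alpha: float) -> str:
    """Canonical catalog key for a Randić exponent, e.g. ``R_-0.5``."""
    return f"R_{alpha:g}"


def compute_all(
    ep: EdgePartition,
    ctx: BalabanContext | None = None,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    params: object = None,
) -> dict[str, IndexValue]:
    """Compute the full index catalog on one edge partition.

    Returns a dict with deterministic key order: the Randić family first
    (one entry per requested ``alpha``), then the named indices, then the
    Balaban index if ``ctx`` was given.  With the default exponents and a
    context this yields 13 entries (R_1 is reported as M2).
    """
    out: dict[str, IndexValue] = {}
    for alpha in alphas:
        out[alpha_key(alpha)] = IndexValue(alpha_key(alpha), randic(ep, alpha), params)
    for name, rule in CATALOG.items():
        if rule.needs_graph_context:
            continue
        out[name] = IndexValue(name, edge_sum(ep, rule), params)
    if ctx is not None:
        out["J"] = IndexValue("J", balaban(ep, ctx), params)
    return out
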