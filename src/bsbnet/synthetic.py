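"""Deterministic synthetic-data generators.

Everything the test surface needs — random simple graphs for partition
validation and noisy rational-model samples for fitter calibration — is
generated here from explicit seeded specs, so no dataset download is ever
required.  Generators are pure functions of their spec: same spec, same
output, with no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "RandomGraphSpec",
    "SyntheticFitSpec",
    "random_graph",
    "synthetic_fit_data",
]


@dataclass(frozen=True)
class RandomGraphSpec:
    """Erdős–Rényi G(n, p) spec with an explicit seed."""

    n_vertices: int
    edge_probability: float
    seed: int


@dataclass(frozen=True)
class SyntheticFitSpec:
    """Noisy samples of a known rational model P/Q (monic Q).

    ``numerator`` and ``denominator_tail`` are in descending powers, the
    denominator's leading 1 implied.  Poles of the true model must lie
    outside ``x_range``.
    """

    numerator: tuple[float, ...]
    denominator_tail: tuple[float, ...]
    x_range: tuple[float, float]
    n_points: int
    noise_sigma: float
    seed: int


def random_graph(spec: RandomGraphSpec) -> list[tuple[str, str]]:
    """Simple undirected G(n, p) edge list with string vertex labels."""
    if spec.n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if not (0.0 < spec.edge_probability <= 1.0):
        raise ValueError("edge probability must be in (0, 1]")
    g = nx.gnp_random_graph(spec.n_vertices, spec.edge_probability, seed=spec.seed)
    return [(f"v{u}", f"v{v}") for u, v in sorted(g.edges())]


def synthetic_fit_data(
    spec: SyntheticFitSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``y = P(x)/Q(x) + Normal(0, sigma)`` on an even x grid.

    Returns ``(x, y, truth)`` where ``truth`` is the noiseless response.
    Rejects specs whose true denominator has a real root inside the
    sampled range.
    """
    lo, hi = spec.x_range
    if not lo < hi:
        raise ValueError("x_range must be increasing")
    if spec.n_points < 2:
        raise ValueError("need at least 2 points")
    if spec.noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")

    den = np.concatenate([[1.0], np.asarray(spec.denominator_tail, float)])
    if den.size > 1:
        roots = np.roots(den)
        real = roots[np.abs(roots.imag) < 1e-9].real
        if np.any((real >= lo) & (real <= hi)):
            raise ValueError(f"true model has a pole inside x_range {spec.x_range}")

    x = np.linspace(lo, hi, spec.n_points)
    truth = np.polyval(np.asarray(spec.numerator, float), x) / np.polyval(den, x)
    rng = np.random.default_rng(spec.seed)
    y = truth + rng.normal(0.0, spec.noise_sigma, size=x.size)
    return x, y, truth
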