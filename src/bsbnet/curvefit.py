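"""Rational-function least squares with the reported goodness-of-fit suite.

The published heat-of-formation models are rational functions
``f(x) = P(x) / Q(x)`` with a monic denominator, fitted to z-score
normalized index series.  This module provides:

* :func:`normalize` — z-score normalization with the sample (n-1)
  standard deviation (the convention that reproduces the published
  normalization constants);
* :func:`fit_rational` — seeded multi-start nonlinear least squares over
  the monic-denominator parameterization;
* :func:`fit_stats` / :func:`confidence_intervals` — SSE, R², adjusted R²,
  RMSE = sqrt(SSE/(n - params)) and t-based 95% coefficient bounds, the
  exact conventions behind the published statistic lines.

Determinism: identical data and :class:`FitOptions` (seed included) give
bitwise-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Normalization",
    "RationalSpec",
    "FittedModel",
    "FitStats",
    "FitOptions",
    "normalize",
    "fit_rational",
    "fit_stats",
    "confidence_intervals",
]


@dataclass(frozen=True)
class Normalization:
    """Z-score parameters: mean, sample (n-1) standard deviation, length."""

    mean: float
    sdev: float
    n: int

    def apply(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sdev

    def invert(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sdev + self.mean


def normalize(series: Sequence[float]) -> tuple[np.ndarray, Normalization]:
    """Z-score a series; raises on constant or too-short input."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    mean = float(np.mean(x))
    sdev = float(np.std(x, ddof=1))
    if sdev == 0.0:
        raise ValueError("cannot normalize a constant series")
    norm = Normalization(mean=mean, sdev=sdev, n=int(x.size))
    return norm.apply(x), norm


@dataclass(frozen=True)
class RationalSpec:
    """Degrees of a rational model ``P_p(x) / Q_q(x)`` with monic Q."""

    num_degree: int
    den_degree: int

    def __post_init__(self) -> None:
        if self.num_degree < 0 or self.den_degree < 0:
            raise ValueError("degrees must be >= 0")

    @property
    def n_params(self) -> int:
        return self.num_degree + self.den_degree + 1


@dataclass(frozen=True)
class FittedModel:
    """A rational model: numerator coefficients (descending powers) and the
    denominator coefficients below its leading 1, plus the x-normalization
    under which the model was fitted (``None`` for raw-x models)."""

    spec: RationalSpec
    numerator: tuple[float, ...]
    denominator_tail: tuple[float, ...]
    normalization: Normalization | None = None
    pole_warning: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)
    name: str | None = None

    @property
    def denominator(self) -> tuple[float, ...]:
        return (1.0,) + tuple(self.denominator_tail)

    def __call__(self, z) -> np.ndarray:
        """Evaluate at already-normalized abscissae."""
        z = np.asarray(z, dtype=float)
        num = np.polyval(self.numerator, z)
        den = np.polyval(self.denominator, z)
        if np.any(np.abs(den) < 1e-12 * max(1.0, float(np.max(np.abs(num), initial=0.0)))):
            raise ZeroDivisionError("evaluation at (or numerically at) a denominator root")
        return num / den

    def evaluate_raw(self, x) -> np.ndarray:
        """Evaluate at raw index values, applying the stored normalization."""
        z = np.asarray(x, dtype=float)
        if self.normalization is not None:
            z = self.normalization.apply(z)
        return self(z)

    def poles(self) -> np.ndarray:
        """Real roots of the denominator."""
        if self.spec.den_degree == 0:
            return np.empty(0)
        roots = np.roots(self.denominator)
        return np.sort(roots[np.abs(roots.imag) < 1e-9].real)


@dataclass(frozen=True)
class FitStats:
    """SSE, R², adjusted R², RMSE = sqrt(SSE/dof), and 95% bounds."""

    sse: float
    r2: float
    adj_r2: float
    rmse: float
    dof: int
    ci95: tuple[tuple[float, float], ...] | None = None


@dataclass(frozen=True)
class FitOptions:
    """Options for the multi-start fit; fixed options + data => fixed result."""

    seed: int = 0
    starts: int = 50
    max_iter: int = 2000
    xtol: float = 1e-12
    ftol: float = 1e-12


def fit_stats(
    residuals: Sequence[float], y: Sequence[float], n_params: int
) -> FitStats:
    """Goodness-of-fit statistics from residuals.

    ``rmse = sqrt(sse / (n - n_params))`` — confirmed by every published
    SSE/RMSE pair; ``r2 = 1 - sse / sum((y - mean(y))^2)``;
    ``adj_r2 = 1 - (1 - r2) (n - 1) / dof``.
    """
    r = np.asarray(residuals, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = r.size
    dof = n - n_params
    if dof < 1:
        raise ValueError(f"residual degrees of freedom {dof} < 1")
    sse = float(r @ r)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof
    rmse = float(np.sqrt(sse / dof))
    return FitStats(sse=sse, r2=r2, adj_r2=adj_r2, rmse=rmse, dof=dof)


def confidence_intervals(
    jacobian: np.ndarray,
    residuals: Sequence[float],
    n_params: int,
    estimates: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-coefficient 95% bounds: estimate +/- t_{0.975, dof} * SE.

    Standard errors come from the residual-variance-scaled inverse of the
    normal-equations matrix J'J.  A singular normal matrix yields infinite
    bounds and an ill-conditioning warning, not an exception.  Returns a
    (k, 2) array of (low, high); when ``estimates`` is omitted the bounds
    are centred on zero (pure half-widths).
    """
    r = np.asarray(residuals, dtype=float)
    jac = np.asarray(jacobian, dtype=float)
    dof = r.size - n_params
    if dof < 1:
        raise ValueError(f"residual degrees of freedom {dof} < 1")
    s2 = float(r @ r) / dof
    jtj = jac.T @ jac
    tq = float(stats.t.ppf(0.975, dof))
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        warnings.warn("singular normal-equations matrix; bounds are infinite")
        se = np.full(jac.shape[1], np.inf)
    half = tq * se
    centre = np.zeros_like(half) if estimates is None else np.asarray(estimates, float)
    return np.column_stack([centre - half, centre + half])


def _rational_residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray, spec: RationalSpec):
    num = theta[: spec.num_degree + 1]
    den = np.concatenate([[1.0], theta[spec.num_degree + 1 :]])
    q = np.polyval(den, x)
    q = np.where(np.abs(q) < 1e-300, 1e-300, q)
    return np.polyval(num, x) / q - y


def _linearized_start(x: np.ndarray, y: np.ndarray, spec: RationalSpec) -> np.ndarray:
    # Classical initialization: solve min || y*Q(x) - P(x) || which is linear
    # in all coefficients once Q is monic.
    p, q = spec.num_degree, spec.den_degree
    cols = [x**i for i in range(p, -1, -1)]
    cols += [-(y * x**j) for j in range(q - 1, -1, -1)]
    design = np.column_stack(cols)
    rhs = y * x**q
    theta, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return theta


def _has_pole_in_range(theta: np.ndarray, x: np.ndarray, spec: RationalSpec) -> bool:
    if spec.den_degree == 0:
        return False
    den = np.concatenate([[1.0], theta[spec.num_degree + 1 :]])
    roots = np.roots(den)
    real = roots[np.abs(roots.imag) < 1e-9].real
    lo, hi = float(np.min(x)), float(np.max(x))
    return bool(np.any((real >= lo) & (real <= hi)))


def fit_rational(
    x: Sequence[float],
    y: Sequence[float],
    spec: RationalSpec,
    opts: FitOptions = FitOptions(),
) -> tuple[FittedModel, FitStats]:
    """Least-squares fit of ``y ~ P(x)/Q(x)`` with monic denominator.

    Multi-start: a deterministic linearized-least-squares start followed by
    ``opts.starts`` seeded standard-normal draws, each refined with
    Levenberg-Marquardt; converged candidates with a denominator root
    inside ``[min x, max x]`` are rejected during selection (if every
    candidate has one, the best is kept and flagged ``pole_warning``).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if xv.size < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} points for {spec.n_params} parameters"
        )

    rng = np.random.default_rng(opts.seed)
    start_points = [_linearized_start(xv, yv, spec)]
    start_points += [rng.standard_normal(spec.n_params) for _ in range(opts.starts)]

    best = None  # (pole_flag, cost, result)
    for theta0 in start_points:
        if not np.all(np.isfinite(theta0)):
            continue
        try:
            res = optimize.least_squares(
                _rational_residuals,
                theta0,
                args=(xv, yv, spec),
                method="lm",
                xtol=opts.xtol,
                ftol=opts.ftol,
                gtol=1e-12,
                max_nfev=opts.max_iter,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        cost = float(np.sum(res.fun**2))
        pole = _has_pole_in_range(res.x, xv, spec)
        key = (pole, cost)
        if best is None or key < (best[0], best[1]):
            best = (pole, cost, res)

    if best is None:
        raise RuntimeError("rational fit failed to converge from any start")

    pole, _, res = best
    theta = res.x
    model = FittedModel(
        spec=spec,
        numerator=tuple(theta[: spec.num_degree + 1]),
        denominator_tail=tuple(theta[spec.num_degree + 1 :]),
        pole_warning=pole,
    )
    residuals = res.fun
    base = fit_stats(residuals, yv, spec.n_params)
    bounds = confidence_intervals(res.jac, residuals, spec.n_params, estimates=theta)
    ci = tuple((float(lo), float(hi)) for lo, hi in bounds)
    statistics = FitStats(
        sse=base.sse,
        r2=base.r2,
        adj_r2=base.adj_r2,
        rmse=base.rmse,
        dof=base.dof,
        ci95=ci,
    )
    return model, statistics
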