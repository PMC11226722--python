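"""Normalization, rational least squares, and goodness-of-fit conventions."""

import numpy as np
import pytest

from bsbnet.curvefit import (
    FitOptions,
    FittedModel,
    Normalization,
    RationalSpec,
    confidence_intervals,
    fit_rational,
    fit_stats,
    normalize,
)
from bsbnet.indices import randic, zagreb1
from bsbnet.partitions import GridParams, bsb_edge_partition
from bsbnet.synthetic import SyntheticFitSpec, synthetic_fit_data


def _diag_series(index_fn):
    return [index_fn(bsb_edge_partition(GridParams(k, k))) for k in range(1, 9)]


def test_normalize_reproduces_published_constants():
    """The published z-score constants use the sample (n-1) deviation."""
    _, norm = normalize(_diag_series(lambda ep: randic(ep, 1)))
    assert norm.mean == 2544
    assert round(norm.sdev) == 2324
    _, norm_m1 = normalize(_diag_series(zagreb1))
    assert norm_m1.mean == 1766
    assert round(norm_m1.sdev) == 1588


def test_normalize_two_point_and_roundtrip():
    z, norm = normalize([-1.0, 1.0])
    assert norm.mean == 0 and norm.sdev == pytest.approx(np.sqrt(2))
    x = np.array([3.0, 7.0, 11.0, 12.5])
    z, norm = normalize(x)
    assert np.mean(z) == pytest.approx(0, abs=1e-12)
    assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-12)
    assert norm.invert(norm.apply(x)) == pytest.approx(x, abs=1e-12)


def test_normalize_degenerate_inputs():
    with pytest.raises(ValueError):
        normalize([5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        normalize([1.0])


def test_fit_stats_zero_residuals():
    s = fit_stats([0.0] * 8, [1.0, 2.0] * 4, 3)
    assert s.sse == 0 and s.r2 == 1 and s.adj_r2 == 1 and s.rmse == 0
    assert s.dof == 5


@pytest.mark.parametrize(
    "sse, n_params, rmse",
    [
        (0.0001569, 5, 0.007233),
        (3.005e-6, 6, 0.001226),
        (2.473e-6, 7, 0.001573),
        (1.864e-7, 7, 0.0004318),
        (7.64e-8, 7, 0.0002764),
    ],
)
def test_rmse_convention_matches_published_pairs(sse, n_params, rmse):
    """RMSE = sqrt(SSE / (n - params)) on 8-point fits, to 4 s.f."""
    residuals = np.zeros(8)
    residuals[0] = np.sqrt(sse)
    s = fit_stats(residuals, np.arange(8.0), n_params)
    assert s.rmse == pytest.approx(rmse, rel=1e-3)
    assert s.rmse**2 * s.dof == pytest.approx(s.sse, rel=1e-10)


def test_fit_stats_dof_error():
    with pytest.raises(ValueError, match="degrees of freedom"):
        fit_stats([0.0] * 4, [1.0, 2.0, 3.0, 4.0], 4)


def test_confidence_intervals_basics():
    # zero residuals -> zero width
    jac = np.ones((4, 1))
    ci = confidence_intervals(jac, np.zeros(4), 1)
    assert ci == pytest.approx(np.zeros((1, 2)))
    # dof = 1 -> t-quantile 12.706; J'J = 2, s^2 = 2 => SE = 1
    jac = np.ones((2, 1))
    ci = confidence_intervals(jac, [1.0, -1.0], 1)
    assert ci[0, 1] == pytest.approx(12.706, abs=1e-3)
    # centring on estimates
    ci = confidence_intervals(jac, [1.0, -1.0], 1, estimates=[5.0])
    assert ci[0] == pytest.approx([5 - 12.7062, 5 + 12.7062], abs=1e-3)


def test_confidence_intervals_singular():
    jac = np.zeros((5, 2))
    with pytest.warns(UserWarning, match="singular"):
        ci = confidence_intervals(jac, np.ones(5), 2)
    assert np.all(np.isinf(ci[:, 1]))


TRUE_NUM = (1.0, -2.0, 0.5)
TRUE_TAIL = (0.3, 4.0)  # x^2 + 0.3x + 4: complex roots, no real pole


def test_noiseless_recovery_and_determinism():
    """Zero-residual fixed point: exact recovery, bitwise-stable reruns."""
    x, y, _ = synthetic_fit_data(
        SyntheticFitSpec(TRUE_NUM, TRUE_TAIL, (-1.5, 1.5), 30, 0.0, seed=11)
    )
    spec = RationalSpec(2, 2)
    opts = FitOptions(seed=3, starts=10)
    model, stats = fit_rational(x, y, spec, opts)
    assert stats.sse <= 1e-16
    theta = np.array(model.numerator + model.denominator_tail)
    truth = np.array(TRUE_NUM + TRUE_TAIL)
    assert theta == pytest.approx(truth, rel=1e-6)
    assert not model.pole_warning
    model2, _ = fit_rational(x, y, spec, opts)
    assert model.numerator == model2.numerator
    assert model.denominator_tail == model2.denominator_tail


def test_fit_insufficient_points():
    with pytest.raises(ValueError, match="at least"):
        fit_rational([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], RationalSpec(2, 2))


def test_eight_point_seven_param_dof_identity():
    """With dof = 1 the RMSE collapses to sqrt(SSE), the convention behind
    the published 1.864e-7 -> 0.0004318 pair."""
    x, y, _ = synthetic_fit_data(
        SyntheticFitSpec((2.0, 1.0), (3.0,), (0.0, 1.0), 8, 0.002, seed=5)
    )
    model, stats = fit_rational(x, y, RationalSpec(4, 2), FitOptions(seed=0, starts=8))
    assert stats.dof == 1
    assert stats.rmse == pytest.approx(np.sqrt(stats.sse), rel=1e-12)


def test_fitted_model_poles_and_evaluation():
    model = FittedModel(
        spec=RationalSpec(0, 1), numerator=(1.0,), denominator_tail=(-2.0,)
    )
    assert model.poles() == pytest.approx([2.0])
    with pytest.raises(ZeroDivisionError):
        model(2.0)
    norm = Normalization(mean=10.0, sdev=2.0, n=8)
    model = FittedModel(
        spec=RationalSpec(1, 0),
        numerator=(3.0, 1.0),
        denominator_tail=(),
        normalization=norm,
    )
    # raw 12 -> z = 1 -> 3*1 + 1
    assert model.evaluate_raw([12.0]) == pytest.approx([4.0])
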