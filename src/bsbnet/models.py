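"""Reported rational models relating heat of formation to each descriptor.

The source publication fits, for each topological index of BS_b, a rational
model ``HOF ~ P(z)/Q(z)`` in the z-score-normalized index and prints the
coefficients with 95% bounds plus SSE / R² / adjusted R² / RMSE.  This
module packages those printed blocks verbatim so they can be evaluated,
audited, and used to reconstruct the (otherwise unpublished) HOF series.

Printing defects are carried as ``notes`` on each model rather than being
silently repaired; the most severe is the ``R_0.5`` block, whose
coefficients (and even normalization constants) duplicate the ``R_-1``
block, so the true fitted ``R_0.5`` model is unrecoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curvefit import FitStats, FittedModel, Normalization, RationalSpec

__all__ = ["PackagedModel", "packaged_models", "packaged_model"]


@dataclass(frozen=True)
class PackagedModel:
    """One printed coefficient block: model, printed stats, printed bounds."""

    model: FittedModel
    stats: FitStats

    @property
    def name(self) -> str:
        return self.model.name or ""


def _pack(
    name: str,
    numerator: tuple[float, ...],
    denominator_tail: tuple[float, ...],
    mean: float,
    sdev: float,
    sse: float,
    rmse: float,
    ci: tuple[tuple[float, float], ...] | None = None,
    notes: tuple[str, ...] = (),
) -> PackagedModel:
    spec = RationalSpec(num_degree=len(numerator) - 1, den_degree=len(denominator_tail))
    model = FittedModel(
        spec=spec,
        numerator=numerator,
        denominator_tail=denominator_tail,
        normalization=Normalization(mean=mean, sdev=sdev, n=8),
        notes=notes,
        name=name,
    )
    stats = FitStats(
        sse=sse, r2=1.0, adj_r2=1.0, rmse=rmse, dof=8 - spec.n_params, ci95=ci
    )
    return PackagedModel(model=model, stats=stats)


_DUP_NOTE = (
    "coefficients duplicated from the R_-1 block (apparent copy-paste); "
    "the stated model form is degree (1, 5) but the printed coefficients "
    "parameterize the (2, 4) R_-1 model, and the normalization constants "
    "printed (40, 33.31) are the R_-1 series', not the R_0.5 series'"
)

_R_M1_COEFFS = dict(
    numerator=(-3.629e5, -9.148e5, -5.745e5),
    denominator_tail=(37.14, -199.8, 1.529e4, 2.233e4),
    ci=(
        (-1.159e8, 1.152e8),
        (-2.919e8, 2.9e8),
        (-1.831e8, 1.819e8),
        (-1.264e4, 1.271e4),
        (-6.453e4, 6.413e4),
        (-4.853e6, 4.883e6),
        (-7.071e6, 7.116e6),
    ),
)

_MODELS: dict[str, PackagedModel] = {
    m.name: m
    for m in (
        _pack(
            "R_1",
            numerator=(-6194.0, -1.538e4, -9424.0),
            denominator_tail=(269.3, 355.6),
            mean=2544.0,
            sdev=2324.0,
            sse=0.0001569,
            rmse=0.007233,
            ci=(
                (-8791.0, -3598.0),
                (-2.234e4, -8411.0),
                (-1.395e4, -4893.0),
                (155.4, 383.3),
                (184.6, 526.5),
            ),
        ),
        _pack(
            "R_-1",
            mean=40.0,
            sdev=33.31,
            sse=5.642e-5,
            rmse=0.007511,
            **_R_M1_COEFFS,
        ),
        _pack(
            "R_0.5",
            mean=40.0,
            sdev=33.31,
            sse=0.0001191,
            rmse=0.01091,
            notes=(_DUP_NOTE,),
            **_R_M1_COEFFS,
        ),
        _pack(
            "R_-0.5",
            numerator=(-5466.0, -6277.0),
            denominator_tail=(-3.389, 4.521, -5.784, 241.0),
            mean=109.0,
            sdev=94.1,
            sse=0.000811,
            rmse=0.02014,
            ci=(
                (-1.534e4, 4409.0),
                (-1.76e4, 5045.0),
                (-5.493, -1.286),
                (-2.579, 11.62),
                (-17.26, 5.692),
                (-194.0, 676.0),
            ),
        ),
        _pack(
            "M1",
            numerator=(-0.01189, 0.05759, -23.06, -56.41, -34.13),
            denominator_tail=(1.294,),
            mean=1766.0,
            sdev=1588.0,
            sse=3.005e-6,
            rmse=0.001226,
            ci=(
                (-0.02355, -0.0002294),
                (0.04042, 0.07477),
                (-23.08, -23.05),
                (-58.1, -54.71),
                (-36.06, -32.2),
                (1.221, 1.367),
            ),
        ),
        _pack(
            "M2",
            numerator=(0.01287, -0.04554, 0.1065, -22.88, -54.91, -32.5),
            denominator_tail=(1.226,),
            mean=2544.0,
            sdev=2324.0,
            sse=2.979e-6,
            rmse=0.001726,
            ci=(
                (-0.06615, 0.09189),
                (-0.1632, 0.07208),
                (-0.008764, 0.2217),
                (-22.94, -22.81),
                (-60.15, -49.68),
                (-38.45, -26.55),
                (1.001, 1.451),
            ),
        ),
        _pack(
            "ABC",
            numerator=(-7.21e4, -2.099e5, -1.454e5),
            denominator_tail=(3082.0, 5553.0),
            mean=208.2,
            sdev=182.9,
            sse=0.0001287,
            rmse=0.00655,
            ci=(
                (-7.081e5, 5.639e5),
                (-1.996e6, 1.576e6),
                (-1.353e6, 1.063e6),
                (-2.413e4, 3.029e4),
                (-4.059e4, 5.17e4),
            ),
            notes=(
                "normalization constants follow the published ABC value table, "
                "whose column deviates from the exact engine series "
                "(engine mean 208.141, sdev 182.86)",
            ),
        ),
        _pack(
            "GA",
            numerator=(-8.657e5, -9.75e5),
            denominator_tail=(29.16, -105.6, 162.7, 3.71e4),
            mean=302.8,
            sdev=269.3,
            sse=0.0001158,
            rmse=0.007609,
            ci=(
                (-8.952e7, 8.778e7),
                (-1.008e8, 9.887e7),
                (-3198.0, 3256.0),
                (-1.1e4, 1.079e4),
                (-1.644e4, 1.676e4),
                (-3.762e6, 3.837e6),
            ),
        ),
        _pack(
            "HM",
            numerator=(0.01079, -0.03862, 0.09268, -22.92, -55.08, -32.68),
            denominator_tail=(1.234,),
            mean=1.028e4,
            sdev=9355.0,
            sse=2.473e-6,
            rmse=0.001573,
            ci=(
                (-0.06226, 0.08383),
                (-0.148, 0.07075),
                (-0.01252, 0.1979),
                (-22.98, -22.86),
                (-60.88, -49.28),
                (-39.26, -26.09),
                (0.9853, 1.483),
            ),
        ),
        _pack(
            "F",
            numerator=(2.861e5, 7.838e5, 5.178e5),
            denominator_tail=(-1.25e4, -1.958e4),
            mean=5196.0,
            sdev=4706.0,
            sse=0.001106,
            rmse=0.0192,
            ci=(
                (-2.254e7, 2.311e7),
                (-6.159e7, 6.316e7),
                (-4.061e7, 4.165e7),
                (-1.01e6, 9.846e5),
                (-1.575e6, 1.536e6),
            ),
        ),
        _pack(
            "J",
            numerator=(-0.0292, 0.1139, -0.3123, -24.4, -56.85, -34.03),
            denominator_tail=(1.335,),
            mean=391.2,
            sdev=312.2,
            sse=1.864e-7,
            rmse=0.0004318,
            ci=(
                (-0.05179, -0.006602),
                (0.08058, 0.1473),
                (-0.3421, -0.2825),
                (-24.42, -24.39),
                (-57.66, -56.05),
                (-34.91, -33.14),
                (1.301, 1.37),
            ),
        ),
        _pack(
            "ReZG1",
            numerator=(-0.01176, 0.04379, -0.1095, -23.66, -57.08, -34.66),
            denominator_tail=(1.334,),
            mean=222.0,
            sdev=190.2,
            sse=7.64e-8,
            rmse=0.0002764,
            ci=(
                (-0.02673, 0.003214),
                (0.01992, 0.06767),
                (-0.1278, -0.09118),
                (-23.66, -23.65),
                (-58.82, -55.34),
                (-36.6, -32.71),
                (1.259, 1.409),
            ),
        ),
        _pack(
            "ReZG2",
            numerator=(-0.01704, 0.07942, -23.0, -56.14, -33.85),
            denominator_tail=(1.281,),
            mean=435.1,
            sdev=393.6,
            sse=5.646e-6,
            rmse=0.00168,
            ci=(
                (-0.03268, -0.0014),
                (0.05661, 0.1022),
                (-23.02, -22.98),
                (-57.74, -54.54),
                (-35.68, -32.02),
                (1.212, 1.351),
            ),
        ),
        _pack(
            "ReZG3",
            numerator=(-0.01933, 0.08897, -22.97, -56.03, -33.74),
            denominator_tail=(1.276,),
            mean=1.561e4,
            sdev=1.412e4,
            sse=7.195e-6,
            rmse=0.001897,
            ci=(
                (-0.03683, -0.001827),
                (0.06356, 0.1144),
                (-22.99, -22.95),
                (-57.61, -54.46),
                (-35.54, -31.94),
                (1.208, 1.344),
            ),
            notes=(
                "normalization constants follow the published ReZG3 value-table "
                "column, which exceeds the stated closed form 648mn-180(m+n)+54 "
                "by 144k at m=n=k (closed-form series: mean 14958)",
            ),
        ),
    )
}


def packaged_models() -> dict[str, PackagedModel]:
    """All reported coefficient blocks, keyed by index name."""
    return dict(_MODELS)


def packaged_model(name: str) -> PackagedModel:
    if name not in _MODELS:
        raise KeyError(
            f"no packaged model for {name!r}; available: {', '.join(_MODELS)}"
        )
    return _MODELS[name]
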