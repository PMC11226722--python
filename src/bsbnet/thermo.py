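"""Heat of formation (HOF) for the benzyl sulfamoyl network.

The per-cell heat of formation scales a standard molar enthalpy by the
number of formula units over the Avogadro constant:

    HOF = (standard molar HOF / N_A) * formula units

The standard molar enthalpy of BS_b itself is not published numerically,
so the package supports two routes: a user-supplied :class:`ThermoSpec`
(absolute energies), or reconstruction of the *normalized* HOF series
through the reported rational curve-fit models (:mod:`bsbnet.models`),
which all quote R² = 1 on the diagonal grid m = n = 1..8.

A YAML/JSON config can drive the series computation; the default mapping
takes formula units proportional to the network size ``12mn``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

from .curvefit import FittedModel
from .partitions import GridParams, bsb_order_size

__all__ = [
    "AVOGADRO",
    "ThermoSpec",
    "hof",
    "hof_series",
    "reconstruct_hof_series",
    "formula_units_from_size",
    "load_thermo_config",
]

#: CODATA value of the Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class ThermoSpec:
    """Inputs of the HOF formula.

    standard_molar_hof : kJ/mol
    avogadro : mol^-1 (> 0)
    formula_units : dimensionless count (> 0)
    """

    standard_molar_hof: float
    avogadro: float = AVOGADRO
    formula_units: float = 1.0

    def __post_init__(self) -> None:
        if self.avogadro <= 0:
            raise ValueError("Avogadro constant must be positive")
        if self.formula_units <= 0:
            raise ValueError("formula-unit count must be positive")


def hof(spec: ThermoSpec) -> float:
    """Heat of formation in kJ: (molar HOF / N_A) * formula units."""
    return spec.standard_molar_hof / spec.avogadro * spec.formula_units


def formula_units_from_size(params: GridParams, per_edge: float = 1.0) -> float:
    """Default formula-unit rule: proportional to the network size 12mn."""
    _, size = bsb_order_size(params)
    return per_edge * size


def hof_series(
    grid: Sequence[GridParams],
    spec_of: Callable[[GridParams], ThermoSpec],
) -> list[tuple[GridParams, float]]:
    """Element-wise HOF over a grid, in the grid's order."""
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if spec_of is None:
        raise ValueError("a GridParams -> ThermoSpec mapping is required")
    return [(p, hof(spec_of(p))) for p in grid]


def reconstruct_hof_series(
    model: FittedModel, index_values: Iterable[float]
) -> list[float]:
    """Evaluate a packaged HOF model at raw index values.

    The model's own normalization is applied to the inputs, so
    ``index_values`` must be on the same (raw) scale as the series the
    model was fitted to.  Because every reported fit quotes R² = 1, the
    result approximates the unpublished normalized HOF series; evaluation
    at a denominator root raises.
    """
    values = np.asarray(list(index_values), dtype=float)
    out = model.evaluate_raw(values)
    if not np.all(np.isfinite(out)):
        raise ZeroDivisionError("model evaluated at or near a pole")
    return [float(v) for v in out]


def load_thermo_config(path: str | Path) -> dict:
    """Read a YAML or JSON thermo config.

    Recognized keys: ``standard_molar_hof`` (kJ/mol, required),
    ``avogadro`` (optional override), ``formula_units_per_edge``
    (optional, default 1.0).
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict) or "standard_molar_hof" not in cfg:
        raise ValueError("config must be a mapping with 'standard_molar_hof'")
    cfg.setdefault("avogadro", AVOGADRO)
    cfg.setdefault("formula_units_per_edge", 1.0)
    return cfg
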