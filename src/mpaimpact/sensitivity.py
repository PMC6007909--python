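"""One-at-a-time sensitivity sweeps over the impact equations.

Each input parameter of a chosen impact equation is varied across its full
range while all other inputs are held at documented constants; the input
axis is standardized to [0, 1] by its range so that slopes are comparable
across parameters, and parameters are ranked by their maximum absolute
finite-difference slope (steeper = more sensitive).

To keep outputs in a realistic window the proximate-impact models fix the
targeted fraction of the population / assemblage / habitat at 5%, and the
ultimate-impact models fix the input proximate impact at 1%; both are
overridable through the sweep constants.  The remaining constants default
to the medians of the shipped fixture parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import ModelInputError

#: Efficacy grid floor: the 1/Eff term is singular at zero, so sweeps over
#: efficacy start at this epsilon rather than 0.
EFF_EPSILON = 0.01

#: Widest recovery-time range swept for biota (years); habitat RT is capped
#: at 20 by construction so its sweep stops there.
RT_MAX_BIOTA = 50.0
RT_MAX_HABITAT = 20.0
INTERACTION_MAX = 5.0


def _population_pi(p: Mapping[str, float]) -> float:
    return (
        (p["m_meth"] + (1.0 - p["m_meth"]) * p["m_hand"])
        / p["eff"]
        * p["targeted_fraction"]
    )


def _assemblage_pi(p: Mapping[str, float]) -> float:
    return (
        (p["m_meth"] + (1.0 - p["m_meth"]) * p["m_hand"])
        * p["suscep"]
        * p["area_fraction"]
    )


def _habitat_pi(p: Mapping[str, float]) -> float:
    return p["p_alt"] * p["area_fraction"]


def _biota_ui(p: Mapping[str, float]) -> float:
    return p["pi"] * (p["rt"] / 2.0) * p["interaction"]


def _habitat_ui(p: Mapping[str, float]) -> float:
    return p["pi"] * (p["rt"] / 2.0)


@dataclass(frozen=True)
class _ModelDef:
    func: Callable[[Mapping[str, float]], float]
    ranges: dict[str, tuple[float, float]]  # sweepable parameters
    constants: dict[str, float]  # defaults, incl. fixed context values


#: Default constants: medians of the fixture parameter tables, plus the
#: fixed 5% targeted fraction / 1% input PI conventions described above.
MODELS: dict[str, _ModelDef] = {
    "population_pi": _ModelDef(
        _population_pi,
        ranges={"m_meth": (0.0, 1.0), "m_hand": (0.0, 1.0), "eff": (EFF_EPSILON, 1.0)},
        constants={"m_meth": 0.33, "m_hand": 0.1, "eff": 0.8, "targeted_fraction": 0.05},
    ),
    "assemblage_pi": _ModelDef(
        _assemblage_pi,
        ranges={"m_meth": (0.0, 1.0), "m_hand": (0.0, 1.0), "suscep": (0.0, 1.0)},
        constants={"m_meth": 0.33, "m_hand": 0.1, "suscep": 0.25, "area_fraction": 0.05},
    ),
    "habitat_pi": _ModelDef(
        _habitat_pi,
        ranges={"p_alt": (0.0, 1.0)},
        constants={"p_alt": 0.33, "area_fraction": 0.05},
    ),
    "population_ui": _ModelDef(
        _biota_ui,
        ranges={"rt": (0.0, RT_MAX_BIOTA), "interaction": (1.0, INTERACTION_MAX)},
        constants={"rt": 10.0, "interaction": 2.0, "pi": 0.01},
    ),
    "assemblage_ui": _ModelDef(
        _biota_ui,
        ranges={"rt": (0.0, RT_MAX_BIOTA), "interaction": (1.0, INTERACTION_MAX)},
        constants={"rt": 10.0, "interaction": 2.0, "pi": 0.01},
    ),
    "habitat_ui": _ModelDef(
        _habitat_ui,
        ranges={"rt": (0.0, RT_MAX_HABITAT)},
        constants={"rt": 10.0, "pi": 0.01},
    ),
}


@dataclass(frozen=True)
class SweepSpec:
    """One one-at-a-time sweep: vary ``parameter`` of ``model`` over
    ``range`` (defaults to the model's full parameter range) with all
    other inputs fixed at ``constants``."""

    model: str
    parameter: str
    n_points: int = 101
    range: tuple[float, float] | None = None
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ModelInputError(
                f"unknown model {self.model!r}; known: {sorted(MODELS)}"
            )
        mdef = MODELS[self.model]
        if self.parameter not in mdef.ranges:
            raise ModelInputError(
                f"model {self.model!r} has no sweepable parameter "
                f"{self.parameter!r}; known: {sorted(mdef.ranges)}"
            )
        if self.n_points < 2:
            raise ModelInputError("n_points must be >= 2")


@dataclass
class SweepResult:
    """Grid evaluation of one sweep plus its slope summary."""

    spec: SweepSpec
    table: pd.DataFrame  # columns: input, standardized_input, output
    max_abs_slope: float


def _effective(spec: SweepSpec) -> tuple[_ModelDef, dict[str, float], tuple[float, float]]:
    mdef = MODELS[spec.model]
    constants = dict(mdef.constants)
    constants.update(spec.constants)
    lo, hi = spec.range if spec.range is not None else mdef.ranges[spec.parameter]
    if spec.parameter == "eff" and lo <= 0:
        raise ModelInputError(
            f"efficacy sweeps must start above 0 (grid floor {EFF_EPSILON})"
        )
    return mdef, constants, (lo, hi)


def one_at_a_time_sweep(spec: SweepSpec) -> SweepResult:
    """Deterministic grid evaluation of one input of one impact equation."""
    mdef, constants, (lo, hi) = _effective(spec)
    grid = np.linspace(lo, hi, spec.n_points)
    std = np.zeros_like(grid) if hi == lo else (grid - lo) / (hi - lo)
    out = np.empty_like(grid)
    for i, v in enumerate(grid):
        p = dict(constants)
        p[spec.parameter] = float(v)
        out[i] = mdef.func(p)
    table = pd.DataFrame(
        {"input": grid, "standardized_input": std, "output": out}
    )
    if hi == lo:
        slope = 0.0
    else:
        slope = float(np.max(np.abs(np.diff(out) / np.diff(std))))
    return SweepResult(spec, table, slope)


def combined_sweep(
    model: str,
    n_points: int = 101,
    constants: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Vary all sweepable inputs of a model simultaneously, each moving
    linearly across its own range along the shared standardized axis."""
    if model not in MODELS:
        raise ModelInputError(f"unknown model {model!r}")
    mdef = MODELS[model]
    base = dict(mdef.constants)
    if constants:
        base.update(constants)
    std = np.linspace(0.0, 1.0, n_points)
    out = np.empty_like(std)
    for i, x in enumerate(std):
        p = dict(base)
        for name, (lo, hi) in mdef.ranges.items():
            p[name] = lo + x * (hi - lo)
        out[i] = mdef.func(p)
    return pd.DataFrame({"standardized_input": std, "output": out})


def sensitivity_ranking(
    model: str,
    constants: Mapping[str, float] | None = None,
    n_points: int = 101,
) -> list[tuple[str, float]]:
    """Rank a model's parameters by maximum absolute finite-difference
    slope over the standardized axis, steepest first."""
    if model not in MODELS:
        raise ModelInputError(f"unknown model {model!r}")
    mdef = MODELS[model]
    results = []
    for name in mdef.ranges:
        spec = SweepSpec(model, name, n_points=n_points, constants=constants or {})
        results.append((name, one_at_a_time_sweep(spec).max_abs_slope))
    return sorted(results, key=lambda kv: kv[1], reverse=True)
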