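"""Cross-over sweeps, optimal and robust baseline durations.

The central design question — should the trial schedule a prospective
baseline period, and how long should it be? — is answered by sweeping the
cross-over time ``t*`` over its admissible range and evaluating the variance
multiplier at each candidate, then reading off the minimum, comparing it with
the no-baseline design, or minimising the worst case over plausible
correlation parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ConfigurationError, CorrelationParams, DesignSpec, TimeEffectSpec
from .variance import DegenerateDesignError, design_variance

__all__ = [
    "VarianceCurve",
    "NoneOrHalfResult",
    "MinimaxResult",
    "variance_curve",
    "none_or_half",
    "minimax_crossover",
]

#: default sweep resolution: 1/96 of the trial period (finer than monthly
#: for a two-year trial)
DEFAULT_GRID_STEP = 1.0 / 96.0


def _candidate(template: DesignSpec, crossover: float) -> DesignSpec:
    if template.no_baseline:
        raise ConfigurationError(
            "sweep template must be a baseline design; the no-baseline design "
            "is evaluated separately as a reference point"
        )
    return replace(template, crossover=crossover)


def _multiplier_or_nan(
    spec: DesignSpec, corr: CorrelationParams, time_effect: TimeEffectSpec
) -> float:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # expected column drops at edges
            return design_variance(spec, corr, time_effect).multiplier
    except DegenerateDesignError:
        return math.nan


@dataclass(frozen=True)
class VarianceCurve:
    """Variance multiplier as a function of cross-over time.

    Grid points where the design is degenerate (no estimable treatment
    effect) carry NaN and are never interpolated.  ``optimum`` is the grid
    minimum, ties broken toward the smaller ``t*`` (shorter baseline).
    """

    crossover_grid: np.ndarray
    multipliers: np.ndarray
    optimum: tuple[float, float]
    no_baseline_point: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"crossover": self.crossover_grid, "multiplier": self.multipliers}
        )


def crossover_grid(
    spec_template: DesignSpec, grid_step: float = DEFAULT_GRID_STEP
) -> np.ndarray:
    """Admissible cross-over times ``t*`` at multiples of `grid_step`.

    The admissible range is ``[closure + implementation, 1]`` so that the
    transition window fits before the cross-over.
    """
    if not grid_step > 0:
        raise ConfigurationError(f"grid_step must be positive, got {grid_step}")
    lo = spec_template.closure + spec_template.implementation
    if lo >= 1.0:
        raise ConfigurationError("transition period fills the whole trial")
    k0 = math.ceil(lo / grid_step - 1e-9)
    k1 = math.floor(1.0 / grid_step + 1e-9)
    grid = np.arange(k0, k1 + 1) * grid_step
    grid = grid[(grid >= lo - 1e-12) & (grid <= 1.0 + 1e-12)]
    if grid.size == 0:
        raise ConfigurationError(
            f"no multiple of grid_step={grid_step} falls in the admissible "
            f"cross-over range [{lo}, 1]"
        )
    return grid


def variance_curve(
    spec_template: DesignSpec,
    corr: CorrelationParams,
    time_effect: TimeEffectSpec,
    grid_step: float = DEFAULT_GRID_STEP,
    include_no_baseline: bool = False,
) -> VarianceCurve:
    """Sweep the cross-over time and evaluate the variance multiplier.

    The optional no-baseline reference point is computed as a distinct
    design (implementation-only delay, no closure), not as the curve's left
    endpoint.
    """
    grid = crossover_grid(spec_template, grid_step)
    mult = np.array(
        [
            _multiplier_or_nan(_candidate(spec_template, t), corr, time_effect)
            for t in grid
        ]
    )
    if not np.any(np.isfinite(mult)):
        raise ConfigurationError("no admissible cross-over time yields an estimable design")
    i = int(np.nanargmin(mult))  # first minimum -> smaller t* on ties
    nb = None
    if include_no_baseline:
        nb_spec = DesignSpec.without_baseline(
            spec_template.m,
            spec_template.implementation,
            spec_template.control_recruits_in_transition,
        )
        nb = _multiplier_or_nan(nb_spec, corr, time_effect)
    return VarianceCurve(
        crossover_grid=grid,
        multipliers=mult,
        optimum=(float(grid[i]), float(mult[i])),
        no_baseline_point=nb,
    )


@dataclass(frozen=True)
class NoneOrHalfResult:
    """Outcome of the 'none or half' rule of thumb.

    Compares the no-baseline design with a design whose cross-over sits at
    half the trial period, picks the smaller variance, and reports how close
    that pick comes to the full-sweep optimum (``efficiency`` is the ratio of
    the chosen multiplier to the optimal one; always >= 1).
    """

    none_multiplier: float
    half_multiplier: float
    choice: str
    chosen_multiplier: float
    optimum: tuple[float, float]
    efficiency: float


def none_or_half(
    spec_template: DesignSpec,
    corr: CorrelationParams,
    time_effect: TimeEffectSpec,
    grid_step: float = DEFAULT_GRID_STEP,
) -> NoneOrHalfResult:
    """Evaluate the heuristic of choosing no baseline or a half-trial baseline."""
    if spec_template.closure + spec_template.implementation > 0.5:
        raise ConfigurationError(
            "the half-trial cross-over is inadmissible: transition longer than half"
        )
    nb_spec = DesignSpec.without_baseline(
        spec_template.m,
        spec_template.implementation,
        spec_template.control_recruits_in_transition,
    )
    none_mult = _multiplier_or_nan(nb_spec, corr, time_effect)
    if math.isnan(none_mult):
        raise ConfigurationError("no-baseline design is degenerate")
    half_mult = _multiplier_or_nan(_candidate(spec_template, 0.5), corr, time_effect)
    if math.isnan(half_mult):
        raise ConfigurationError("half-trial cross-over design is degenerate")
    curve = variance_curve(spec_template, corr, time_effect, grid_step)
    best = min(curve.optimum[1], none_mult)
    if none_mult <= half_mult:
        choice, chosen = "none", none_mult
    else:
        choice, chosen = "half", half_mult
    return NoneOrHalfResult(
        none_multiplier=none_mult,
        half_multiplier=half_mult,
        choice=choice,
        chosen_multiplier=chosen,
        optimum=curve.optimum,
        efficiency=chosen / best,
    )


@dataclass(frozen=True)
class MinimaxResult:
    """Cross-over time minimising the worst-case variance over (rho, tau)."""

    crossover: float
    worst_case_multiplier: float
    crossover_grid: np.ndarray
    worst_case_curve: np.ndarray


def minimax_crossover(
    spec_template: DesignSpec,
    rho_values,
    tau_values,
    time_effect: TimeEffectSpec,
    grid_step: float = DEFAULT_GRID_STEP,
    sigma2: float = 1.0,
) -> MinimaxResult:
    """Minimise the maximum multiplier over a grid of plausible (rho, tau).

    Useful when the intracluster correlation and its decay are uncertain at
    the design stage: for each candidate cross-over the worst case over the
    parameter grid is recorded, and the cross-over with the smallest worst
    case is returned.
    """
    rho_values = list(rho_values)
    tau_values = list(tau_values)
    if not rho_values or not tau_values:
        raise ConfigurationError("rho_values and tau_values must be nonempty")
    grid = crossover_grid(spec_template, grid_step)
    worst = np.full(grid.size, -np.inf)
    for rho in rho_values:
        for tau in tau_values:
            corr = CorrelationParams(rho=rho, tau=tau, sigma2=sigma2)
            curve = variance_curve(spec_template, corr, time_effect, grid_step)
            worst = np.maximum(worst, curve.multipliers)  # NaN propagates
    if not np.any(np.isfinite(worst)):
        raise ConfigurationError("no cross-over time is admissible for every parameter set")
    i = int(np.nanargmin(worst))
    return MinimaxResult(
        crossover=float(grid[i]),
        worst_case_multiplier=float(worst[i]),
        crossover_grid=grid,
        worst_case_curve=worst,
    )
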