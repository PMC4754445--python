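"""Reproduction-error analysis and the optimal memory weight.

The mean squared reproduction error decomposes as

    MSE_r = E(Var(r|T)) + E(bias(T)^2)

where both expectations run over the uniform stimulus set.  Setting
``d(MSE_r)/da = 0`` gives the memory weight that minimizes the error,

    a_min = 2 - sqrt((A_m/A_r) * ((sigma_m/A_m)^2 * E(T)/Var(T) + 1))

i.e. the optimal amount of regression to the mean grows (``a_min`` falls)
with the inverse measurement SNR ``sigma_m/A_m`` (regression effect) and
with the mean-to-variance ratio of the stimulus distribution (range
effect).  The reproduction noise ``sigma_r`` inflates the error but leaves
``a_min`` untouched, because the memory update precedes the reproduction
stage.  Values of ``a_min`` outside (0, 1] mean no interior optimum exists;
they are reported as-is and flagged infeasible, and a brute-force grid
search over (0, 1] serves as the independent oracle.

The bias-squared term is assembled by numerically averaging the squared
per-stimulus bias over the stimulus set (exact for a discrete set); the
equivalent closed form ``(1 - a*A_m/A_r)^2*Var(T) + (1 - A_m/A_r)^2*E(T)^2``
is exposed separately for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .analytics import (
    StimulusSet,
    reproduction_bias,
    reproduction_variance,
)
from .model import ModelParams

__all__ = [
    "MseDecomposition",
    "OptimalityReport",
    "mse",
    "expected_reproduction_variance",
    "mean_squared_bias_closed_form",
    "a_min_closed_form",
    "grid_search_a",
    "optimality_report",
    "sweep",
    "sweep_table",
]

SWEEP_AXES = ("dispersion_ratio", "snr_inverse", "drift_ratio", "noise_reproduce")


class MseDecomposition(NamedTuple):
    """``total = variance_term + bias_sq_term`` (the Pythagorean split)."""

    total: float
    variance_term: float
    bias_sq_term: float


def mse(
    params: ModelParams,
    stim_set: StimulusSet,
    at_weight: float | None = None,
) -> MseDecomposition:
    """Mean squared reproduction error and its variance/bias^2 split.

    ``at_weight`` overrides ``params.memory_weight`` when given.  The
    variance term averages the per-stimulus reproduction variance; the bias
    term averages the squared per-stimulus bias.
    """
    if at_weight is not None:
        if not 0 < at_weight <= 1:
            raise ValueError("at_weight must lie in (0, 1]")
        params = params.replace(memory_weight=at_weight)
    T = stim_set.array
    variance_term = float(np.mean(reproduction_variance(T, params, stim_set)))
    bias_sq_term = float(np.mean(reproduction_bias(T, params, stim_set) ** 2))
    return MseDecomposition(variance_term + bias_sq_term, variance_term, bias_sq_term)


def expected_reproduction_variance(
    params: ModelParams, stim_set: StimulusSet
) -> float:
    """Closed form for ``E(Var(r|T))`` over the stimulus set.

    Algebraically identical to averaging the per-stimulus reproduction
    variance; kept as an independent expression for consistency tests.
    """
    a = params.memory_weight
    A_m, A_r = params.drift_measure, params.drift_reproduce
    s_m2, s_r2 = params.noise_measure**2, params.noise_reproduce**2
    total_m_var = A_m**2 * stim_set.variance + s_m2 * stim_set.mean
    return (
        (A_m * s_r2 / A_r**3 + a**2 * s_m2 / A_r**2) * stim_set.mean
        + total_m_var * a * (1 - a) ** 2 / (A_r**2 * (2 - a))
    )


def mean_squared_bias_closed_form(params: ModelParams, stim_set: StimulusSet) -> float:
    """Closed form for ``E(bias(T)^2)`` over the stimulus set.

    Expanding ``E[(-(1-a*g)T + (1-a)*g*E(T))^2]`` with ``g = A_m/A_r``
    gives ``(1-a*g)^2*Var(T) + (1-g)^2*E(T)^2``; the second term is the
    memory-independent penalty of mismatched drifts.
    """
    a = params.memory_weight
    g = params.drift_ratio
    return (1 - a * g) ** 2 * stim_set.variance + (1 - g) ** 2 * stim_set.mean**2


def a_min_closed_form(params: ModelParams, stim_set: StimulusSet) -> float:
    """Memory weight minimizing the MSE (no clamping into (0, 1]).

    Stationary point of the MSE in ``a``:
    ``a_min = 2 - sqrt((A_m/A_r)*((sigma_m/A_m)^2 * E(T)/Var(T) + 1))``.
    Results outside (0, 1] indicate that no interior optimum is attainable
    for these parameters.
    """
    g = params.drift_ratio
    rel_noise = params.snr_inverse**2 * stim_set.dispersion_ratio
    return 2.0 - math.sqrt(g * (rel_noise + 1.0))


def grid_search_a(
    params: ModelParams, stim_set: StimulusSet, grid_step: float = 1e-3
) -> float:
    """Brute-force argmin of the MSE over ``a in {step, 2*step, ..., <=1}``.

    Ties break toward smaller ``a``.  Serves as the independent oracle for
    :func:`a_min_closed_form` and as the fallback optimum when the closed
    form lies outside (0, 1].
    """
    if not 0 < grid_step <= 0.1 + 1e-12:
        raise ValueError("grid_step must lie in (0, 0.1]")
    n = int(math.floor(1.0 / grid_step + 1e-9))
    grid = grid_step * np.arange(1, n + 1)
    grid = grid[grid <= 1.0 + 1e-12]
    totals = np.array([mse(params, stim_set, at_weight=a).total for a in grid])
    return float(grid[int(np.argmin(totals))])


@dataclass
class OptimalityReport:
    """Error analysis for one parameter set and stimulus distribution."""

    params: ModelParams
    stim_set: StimulusSet
    a_min_closed_form: float
    a_min_grid: float
    feasible: bool
    #: closed-form optimum if it lies in (0, 1], else the grid-search best
    a_min_feasible: float
    mse_at_optimum: MseDecomposition
    #: (a, MSE, variance term, bias^2 term) curve over the search grid
    mse_curve: pd.DataFrame = field(repr=False)
    snr_inverse: float = 0.0
    drift_ratio: float = 0.0
    varied_name: str | None = None
    varied_value: float | None = None

    @property
    def rmse(self) -> float:
        return math.sqrt(self.mse_at_optimum.total)

    @property
    def sqrt_variance_term(self) -> float:
        return math.sqrt(self.mse_at_optimum.variance_term)

    @property
    def bias_magnitude(self) -> float:
        """Root of the mean squared bias (the BIAS leg of the quarter circle)."""
        return math.sqrt(self.mse_at_optimum.bias_sq_term)


def optimality_report(
    params: ModelParams,
    stim_set: StimulusSet,
    grid_step: float = 1e-3,
) -> OptimalityReport:
    """Closed-form and grid-search optima plus the full MSE(a) curve."""
    closed = a_min_closed_form(params, stim_set)
    grid_best = grid_search_a(params, stim_set, grid_step=grid_step)
    feasible = 0.0 < closed <= 1.0
    a_used = closed if feasible else grid_best
    decomposition = mse(params, stim_set, at_weight=a_used)

    n = int(math.floor(1.0 / grid_step + 1e-9))
    grid = grid_step * np.arange(1, n + 1)
    rows = [mse(params, stim_set, at_weight=float(a)) for a in grid]
    curve = pd.DataFrame(
        {
            "a": grid,
            "mse": [r.total for r in rows],
            "variance_term": [r.variance_term for r in rows],
            "bias_sq_term": [r.bias_sq_term for r in rows],
        }
    )
    return OptimalityReport(
        params=params,
        stim_set=stim_set,
        a_min_closed_form=closed,
        a_min_grid=grid_best,
        feasible=feasible,
        a_min_feasible=a_used,
        mse_at_optimum=decomposition,
        mse_curve=curve,
        snr_inverse=params.snr_inverse,
        drift_ratio=params.drift_ratio,
    )


def _two_point_set(mean: float, variance: float) -> StimulusSet:
    """Symmetric two-point stimulus set with the requested exact moments."""
    half_width = math.sqrt(variance)
    if mean - half_width <= 0:
        raise ValueError("requested moments imply non-positive stimuli")
    return StimulusSet((mean - half_width, mean + half_width))


def sweep(
    params: ModelParams,
    stim_set: StimulusSet,
    vary: str,
    values: Sequence[float],
    grid_step: float = 1e-2,
) -> list[OptimalityReport]:
    """Optimality reports along one parameter axis.

    ``vary`` is one of ``dispersion_ratio`` (rebuilds a two-point stimulus
    set with the same mean and variance ``E(T)/value``), ``snr_inverse``
    (sets ``sigma_m = value * A_m``), ``drift_ratio`` (sets
    ``A_r = A_m / value``, so the measurement SNR is untouched), or
    ``noise_reproduce`` (sets ``sigma_r = value``).
    """
    if vary not in SWEEP_AXES:
        raise ValueError(f"vary must be one of {SWEEP_AXES}")
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    if not all(v > 0 for v in values) and vary != "noise_reproduce":
        raise ValueError("swept values must be > 0")
    if vary == "noise_reproduce" and not all(v >= 0 for v in values):
        raise ValueError("noise_reproduce values must be >= 0")

    reports = []
    for value in values:
        p, s = params, stim_set
        if vary == "dispersion_ratio":
            s = _two_point_set(stim_set.mean, stim_set.mean / value)
        elif vary == "snr_inverse":
            p = params.replace(noise_measure=value * params.drift_measure)
        elif vary == "drift_ratio":
            p = params.replace(drift_reproduce=params.drift_measure / value)
        elif vary == "noise_reproduce":
            p = params.replace(noise_reproduce=value)
        report = optimality_report(p, s, grid_step=grid_step)
        report.varied_name = vary
        report.varied_value = float(value)
        reports.append(report)
    return reports


def sweep_table(reports: Sequence[OptimalityReport]) -> pd.DataFrame:
    """Flatten sweep reports for CSV serialization."""
    return pd.DataFrame(
        {
            "varied_name": [r.varied_name for r in reports],
            "varied_value": [r.varied_value for r in reports],
            "a_min_closed": [r.a_min_closed_form for r in reports],
            "a_min_grid": [r.a_min_grid for r in reports],
            "mse": [r.mse_at_optimum.total for r in reports],
            "rmse": [r.rmse for r in reports],
            "sqrt_var_term": [r.sqrt_variance_term for r in reports],
            "bias_term": [r.bias_magnitude for r in reports],
            "feasible": [r.feasible for r in reports],
        }
    )
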