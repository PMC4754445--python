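"""Closed-form stationary predictions for the two-stage model.

All formulas hold in the stationary (many-preceding-trials) limit of a
session with randomized stimulus presentation: stimuli drawn independently
and uniformly from a discrete set with population mean ``E(T)`` and variance
``Var(T)``.  Writing ``a`` for the memory weight and ``g = A_m/A_r`` for the
drift ratio, the key results are

* threshold mean      ``E(theta|T) = a*A_m*T + (1-a)*A_m*E(T)``
* threshold variance  ``Var(theta|T) = a^2*sigma_m^2*T
  + [A_m^2*Var(T) + sigma_m^2*E(T)] * a*(1-a)^2/(2-a)``
* reproduction mean   ``E(r|T) = a*g*T + (1-a)*g*E(T)`` — linear in ``T``
  with slope ``a*g``; slopes below one are the regression (central
  tendency) effect
* reproduction bias   ``E(r|T) - T``, which flips sign across ``E(T)`` for
  matched drifts
* reproduction variance (law of total variance over the random threshold),
  increasing in ``T`` — scalar variability
* sequential bias: conditioning on the previous stimulus adds
  ``a*(1-a)*g*(T_prev - E(T))`` to the bias.

The full first-passage density under a random threshold has no closed form;
only the first two moments are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams

__all__ = [
    "StimulusSet",
    "PredictionSet",
    "threshold_mean",
    "threshold_variance",
    "reproduction_mean",
    "reproduction_bias",
    "reproduction_variance",
    "expected_overall_bias",
    "sequential_bias",
    "sequential_slope",
    "measurement_total_variance",
    "predict",
]


@dataclass(frozen=True)
class StimulusSet:
    """A discrete set of magnitudes presented with equal probability.

    Moments are population moments of the set under uniform weighting (not
    sample moments of a realized sequence), which makes the stationary
    predictions independent of any particular presentation order.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size < 2:
            raise ValueError("a stimulus set needs at least two values")
        if not np.all(vals > 0):
            raise ValueError("all stimulus values must be > 0")
        if np.var(vals) <= 0:
            raise ValueError("stimulus values must not all be equal")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @classmethod
    def from_range(cls, range_min: float, range_max: float, k: int = 11) -> "StimulusSet":
        """``k`` evenly spaced magnitudes spanning [range_min, range_max]."""
        if not 0 < range_min < range_max:
            raise ValueError("need 0 < range_min < range_max")
        if k < 2:
            raise ValueError("k must be >= 2")
        return cls(tuple(np.linspace(range_min, range_max, k)))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        """E(T) in ms."""
        return float(np.mean(self.array))

    @property
    def variance(self) -> float:
        """Var(T) in ms^2 (population variance)."""
        return float(np.var(self.array))

    @property
    def dispersion_ratio(self) -> float:
        """E(T)/Var(T) in 1/ms — the inverse index of dispersion.

        Larger values mean a narrower (harder to discriminate) stimulus
        distribution and drive stronger optimal regression (range effect).
        """
        return self.mean / self.variance


def threshold_mean(stimulus, params: ModelParams, stim_set: StimulusSet):
    """Stationary mean of the reproduction threshold given stimulus ``T``."""
    a = params.memory_weight
    return params.drift_measure * (a * np.asarray(stimulus) + (1 - a) * stim_set.mean)


def threshold_variance(stimulus, params: ModelParams, stim_set: StimulusSet):
    """Stationary variance of the threshold given stimulus ``T``.

    Combines the current measurement's variance (weight ``a**2``) with the
    geometric-series accumulation of past measurement variability; the
    latter involves the total measurement variance
    ``A_m^2*Var(T) + sigma_m^2*E(T)``.
    """
    a = params.memory_weight
    total_m_var = measurement_total_variance(params, stim_set)
    history = total_m_var * a * (1 - a) ** 2 / (2 - a)
    return a**2 * params.noise_measure**2 * np.asarray(stimulus) + history


def reproduction_mean(stimulus, params: ModelParams, stim_set: StimulusSet):
    """Stationary mean reproduction: linear in ``T`` with slope ``a*A_m/A_r``."""
    a = params.memory_weight
    g = params.drift_ratio
    return a * g * np.asarray(stimulus) + (1 - a) * g * stim_set.mean


def reproduction_bias(stimulus, params: ModelParams, stim_set: StimulusSet):
    """Mean reproduction minus stimulus; sign flips across E(T) for matched drifts."""
    return reproduction_mean(stimulus, params, stim_set) - np.asarray(stimulus)


def reproduction_variance(stimulus, params: ModelParams, stim_set: StimulusSet):
    """Stationary reproduction variance by the law of total variance.

    ``Var(r|T) = E(Var(r|theta)) + Var(E(r|theta))`` over the random
    threshold; increases monotonically in ``T`` (scalar variability, with a
    square-root-law standard deviation).
    """
    a = params.memory_weight
    A_m, A_r = params.drift_measure, params.drift_reproduce
    s_m2, s_r2 = params.noise_measure**2, params.noise_reproduce**2
    total_m_var = measurement_total_variance(params, stim_set)
    slope = a * A_m * s_r2 / A_r**3 + a**2 * s_m2 / A_r**2
    offset = (1 - a) * stim_set.mean * A_m * s_r2 / A_r**3
    history = total_m_var * a * (1 - a) ** 2 / (A_r**2 * (2 - a))
    return slope * np.asarray(stimulus) + offset + history


def expected_overall_bias(
    params: ModelParams, stim_set: StimulusSet
) -> tuple[float, float]:
    """Grand averages over the stimulus set: ``(E(mean r), E(bias))``.

    ``E(mean r) = (A_m/A_r)*E(T)`` and ``E(bias) = (A_m/A_r - 1)*E(T)``:
    drift mismatch produces overall over- (ratio > 1) or under-estimation
    (ratio < 1), independent of the memory weight.
    """
    g = params.drift_ratio
    return g * stim_set.mean, (g - 1) * stim_set.mean


def sequential_slope(params: ModelParams) -> float:
    """Slope of the conditional bias on ``T_prev - E(T)``: ``a*(1-a)*A_m/A_r``.

    Vanishes at ``a = 1`` (no memory) and in the limit of small ``a``.
    """
    a = params.memory_weight
    return a * (1 - a) * params.drift_ratio


def sequential_bias(
    stimulus, prev_stimulus, params: ModelParams, stim_set: StimulusSet
):
    """Bias conditioned on the immediately preceding stimulus."""
    delta_prev = np.asarray(prev_stimulus) - stim_set.mean
    return (
        reproduction_bias(stimulus, params, stim_set)
        + sequential_slope(params) * delta_prev
    )


def measurement_total_variance(params: ModelParams, stim_set: StimulusSet) -> float:
    """Marginal variance of measurements over a randomized session.

    By the law of total variance over the random stimulus,
    ``Var(m) = sigma_m^2*E(T) + A_m^2*Var(T)``.
    """
    return (
        params.noise_measure**2 * stim_set.mean
        + params.drift_measure**2 * stim_set.variance
    )


@dataclass
class PredictionSet:
    """Per-stimulus analytic predictions plus grand averages."""

    params: ModelParams
    stim_set: StimulusSet
    table: pd.DataFrame = field(repr=False)
    expected_mean_reproduction: float
    expected_bias: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), index=False)


def predict(params: ModelParams, stim_set: StimulusSet) -> PredictionSet:
    """Evaluate all stationary predictions over a stimulus set."""
    T = stim_set.array
    table = pd.DataFrame(
        {
            "stimulus_ms": T,
            "pred_mean_ms": reproduction_mean(T, params, stim_set),
            "pred_bias_ms": reproduction_bias(T, params, stim_set),
            "pred_var_ms2": reproduction_variance(T, params, stim_set),
            "pred_threshold_mean": threshold_mean(T, params, stim_set),
            "pred_threshold_var": threshold_variance(T, params, stim_set),
        }
    )
    exp_mean, exp_bias = expected_overall_bias(params, stim_set)
    return PredictionSet(
        params=params,
        stim_set=stim_set,
        table=table,
        expected_mean_reproduction=exp_mean,
        expected_bias=exp_bias,
    )
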