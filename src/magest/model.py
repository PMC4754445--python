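"""Stochastic simulation of a single magnitude-estimation trial.

A trial has two stages, both modelled as drift-diffusion (noisy integrator)
processes:

1. *Measurement*: while the stimulus (e.g. a temporal interval of ``T`` ms)
   is present, an accumulator integrates a constant drift ``A_m`` corrupted
   by Wiener noise of amplitude ``sigma_m``.  The accumulator state at
   stimulus offset is the internal measurement ``m ~ N(A_m*T, sigma_m**2*T)``.
2. *Reproduction*: a second accumulator with drift ``A_r`` and noise
   ``sigma_r`` runs freely from zero until it first crosses a threshold from
   below; the first-passage time is the reproduced magnitude.  For a single
   absorbing bound the first-passage time is inverse-Gaussian distributed.

The two stages are linked by the threshold, which acts as a reference
memory: on every trial it is updated as an exponentially weighted average of
the current measurement and the previous threshold,
``theta_n = a*m_n + (1-a)*theta_{n-1}`` with ``theta_0 = m_0`` and memory
weight ``a`` in (0, 1].

Each stage can be simulated in two interchangeable modes: ``"exact"``
(sampling the known endpoint / first-passage distributions directly) and
``"path"`` (Euler–Maruyama integration of the stochastic differential
equations, default step 5 ms).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .analytics import StimulusSet

__all__ = [
    "DegenerateThresholdError",
    "DegenerateThresholdWarning",
    "ModelParams",
    "TrialRecord",
    "SessionResult",
    "sample_measurement_exact",
    "simulate_measurement_path",
    "update_threshold",
    "sample_reproduction_exact",
    "simulate_reproduction_path",
    "run_session",
]


class DegenerateThresholdError(ValueError):
    """Raised when a reproduction threshold is non-positive.

    The model assumes a drift-dominated regime in which measurements, and
    hence thresholds, stay positive; a non-positive threshold cannot be
    crossed from below and signals a violation of that assumption.
    """


class DegenerateThresholdWarning(RuntimeWarning):
    """Emitted by :func:`run_session` when a trial's threshold is <= 0."""


@dataclass(frozen=True, kw_only=True)
class ModelParams:
    """The model constants governing both integrator stages.

    Parameters
    ----------
    drift_measure
        Measurement drift ``A_m`` (accumulator units per ms), > 0.
    noise_measure
        Measurement diffusion amplitude ``sigma_m`` (per sqrt(ms)), >= 0.
    drift_reproduce
        Reproduction drift ``A_r`` (accumulator units per ms), > 0.
    noise_reproduce
        Reproduction diffusion amplitude ``sigma_r`` (per sqrt(ms)), >= 0.
    memory_weight
        Reference-memory update weight ``a`` in (0, 1].  ``a = 1`` keeps no
        history (the threshold equals the current measurement); small ``a``
        averages over many past trials.  ``a = 0`` is excluded: it would
        freeze the reference at the very first measurement forever.
    dt
        Euler time step in ms for path-mode simulation (default 5 ms).
    """

    drift_measure: float = 0.25
    noise_measure: float = 1.0
    drift_reproduce: float = 0.25
    noise_reproduce: float = 0.5
    memory_weight: float
    dt: float = 5.0

    def __post_init__(self) -> None:
        if not self.drift_measure > 0:
            raise ValueError("drift_measure must be > 0")
        if not self.drift_reproduce > 0:
            raise ValueError("drift_reproduce must be > 0")
        if self.noise_measure < 0 or self.noise_reproduce < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0 < self.memory_weight <= 1:
            raise ValueError("memory_weight must lie in (0, 1]; a = 0 is excluded")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    @property
    def drift_ratio(self) -> float:
        """Drift mismatch ``A_m / A_r``; != 1 produces overall over/under-estimation."""
        return self.drift_measure / self.drift_reproduce

    @property
    def snr_inverse(self) -> float:
        """Inverse signal-to-noise ratio of measurement, ``sigma_m / A_m`` (sqrt(ms)).

        The model's analogue of the Weber fraction.
        """
        return self.noise_measure / self.drift_measure

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: stimulus, measurement endpoint, threshold, reproduction.

    ``reproduction`` is ``None`` when the trial produced no response (the
    threshold was non-positive, or path-mode integration hit its time cap).
    """

    index: int
    stimulus: float
    measurement: float
    threshold: float
    reproduction: float | None
    mode: str

    @property
    def is_missing(self) -> bool:
        return self.reproduction is None


@dataclass
class SessionResult:
    """Ordered trial records plus the provenance needed to replay them."""

    trials: list[TrialRecord]
    params: ModelParams
    seed: int
    mode: str
    stimulus_set: "StimulusSet | None" = None

    @property
    def n_missing(self) -> int:
        return sum(t.is_missing for t in self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "stimulus_ms": [t.stimulus for t in self.trials],
                "measurement": [t.measurement for t in self.trials],
                "threshold": [t.threshold for t in self.trials],
                "reproduction_ms": [
                    math.nan if t.reproduction is None else t.reproduction
                    for t in self.trials
                ],
                "mode": [t.mode for t in self.trials],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the trial table as CSV plus a sidecar ``<path>.json`` manifest.

        Missing reproductions are written as empty fields.
        """
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {
            "params": self.params.to_dict(),
            "seed": self.seed,
            "mode": self.mode,
            "stimulus_set": (
                None if self.stimulus_set is None else list(self.stimulus_set.values)
            ),
            "n_trials": len(self.trials),
            "n_missing": self.n_missing,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


# ---------------------------------------------------------------------------
# Measurement stage
# ---------------------------------------------------------------------------

def sample_measurement_exact(
    stimulus: float, params: ModelParams, rng: np.random.Generator
) -> float:
    """Draw the measurement-accumulator endpoint from its exact distribution.

    Integrating the measurement SDE over the stimulus duration ``T`` gives a
    Gaussian endpoint ``m_T ~ N(A_m*T, sigma_m**2 * T)``.
    """
    if not stimulus > 0:
        raise ValueError("stimulus must be > 0")
    return (
        params.drift_measure * stimulus
        + params.noise_measure * math.sqrt(stimulus) * rng.standard_normal()
    )


def _step_sizes(duration: float, dt: float) -> np.ndarray:
    """Euler steps covering ``duration`` exactly: full ``dt`` steps plus a
    scaled final partial step so the integrated time equals ``duration``."""
    n_full = int(math.floor(duration / dt + 1e-12))
    rem = duration - n_full * dt
    if rem > 1e-9 * max(dt, 1.0):
        return np.concatenate([np.full(n_full, dt), [rem]])
    return np.full(max(n_full, 1), duration / max(n_full, 1))


def simulate_measurement_path(
    stimulus: float, params: ModelParams, rng: np.random.Generator
) -> float:
    """Euler-integrate the measurement SDE from 0 to stimulus offset.

    Uses steps of ``params.dt`` with the final partial step scaled so the
    total integrated time is exactly the stimulus duration.  The endpoint
    distribution coincides with :func:`sample_measurement_exact` (the Euler
    scheme is distribution-exact for constant drift and additive noise).
    """
    if not stimulus > 0:
        raise ValueError("stimulus must be > 0")
    if params.dt > stimulus:
        raise ValueError("dt must not exceed the stimulus duration")
    steps = _step_sizes(stimulus, params.dt)
    draws = rng.standard_normal(steps.size)
    return float(
        params.drift_measure * stimulus
        + params.noise_measure * np.sum(np.sqrt(steps) * draws)
    )


# ---------------------------------------------------------------------------
# Reference-memory update
# ---------------------------------------------------------------------------

def update_threshold(
    measurement: float, prev_threshold: float, memory_weight: float
) -> float:
    """Exponentially weighted reference update.

    ``theta_n = a*m_n + (1-a)*theta_{n-1}``.  The weight must lie in (0, 1];
    ``a = 0`` is excluded (it would never incorporate new stimuli).
    """
    if not 0 < memory_weight <= 1:
        raise ValueError("memory_weight must lie in (0, 1]")
    return memory_weight * measurement + (1.0 - memory_weight) * prev_threshold


# ---------------------------------------------------------------------------
# Reproduction stage
# ---------------------------------------------------------------------------

def sample_reproduction_exact(
    threshold: float, params: ModelParams, rng: np.random.Generator
) -> float:
    """Draw a first-passage time of the reproduction accumulator exactly.

    For drift ``A_r`` and a single absorbing bound at ``theta > 0`` the
    first-passage time is inverse Gaussian with mean ``theta/A_r`` and
    variance ``theta*sigma_r**2/A_r**3`` (shape ``lambda = theta**2/sigma_r**2``).
    """
    if not threshold > 0:
        raise DegenerateThresholdError(
            "non-positive threshold cannot be crossed from below"
        )
    mean = threshold / params.drift_reproduce
    if params.noise_reproduce == 0:
        return mean
    shape = threshold**2 / params.noise_reproduce**2
    return float(rng.wald(mean, shape))


def simulate_reproduction_path(
    threshold: float,
    params: ModelParams,
    rng: np.random.Generator,
    max_time: float | None = None,
) -> float | None:
    """Euler-integrate the reproduction SDE until the threshold is crossed.

    The crossing time is linearly interpolated between the last
    sub-threshold and the first supra-threshold Euler point, which removes
    the O(dt) positive bias of reporting the full crossing step.  Returns
    ``None`` (missing response) if ``max_time`` is reached first; the
    default cap is ``10 * threshold / A_r``, generous in the
    drift-dominated regime the model assumes.
    """
    if not threshold > 0:
        raise DegenerateThresholdError(
            "non-positive threshold cannot be crossed from below"
        )
    if max_time is None:
        max_time = 10.0 * threshold / params.drift_reproduce
    if not max_time > 0:
        raise ValueError("max_time must be > 0")

    dt = params.dt
    drift = params.drift_reproduce * dt
    sigma_step = params.noise_reproduce * math.sqrt(dt)
    n_steps = int(math.ceil(max_time / dt))
    chunk = 256
    pos = 0.0
    done = 0
    while done < n_steps:
        n = min(chunk, n_steps - done)
        increments = drift + sigma_step * rng.standard_normal(n)
        path = pos + np.cumsum(increments)
        crossed = np.nonzero(path >= threshold)[0]
        if crossed.size:
            j = int(crossed[0])
            before = pos if j == 0 else float(path[j - 1])
            after = float(path[j])
            frac = (threshold - before) / (after - before)
            t_cross = (done + j + frac) * dt
            return t_cross if t_cross <= max_time else None
        pos = float(path[-1])
        done += n
    return None


# ---------------------------------------------------------------------------
# Session orchestration
# ---------------------------------------------------------------------------

def run_session(
    sequence: Sequence[float],
    params: ModelParams,
    mode: str = "exact",
    seed: int = 0,
    stimulus_set: "StimulusSet | None" = None,
    max_time: float | None = None,
) -> SessionResult:
    """Simulate a full session: measure, update the reference, reproduce.

    A single seeded generator is consumed in trial order (measurement draw
    then reproduction draw), so a session is bit-reproducible from
    ``(sequence, params, mode, seed)``.

    Trials whose threshold is non-positive (possible outside the
    drift-dominated regime) record a missing reproduction and emit a
    :class:`DegenerateThresholdWarning`; the reference memory is still
    updated with the trial's measurement, so the update dynamics are
    preserved and the violation stays observable via ``n_missing``.
    """
    if mode not in ("exact", "path"):
        raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'path'")
    sequence = np.asarray(sequence, dtype=float)
    if sequence.size == 0:
        raise ValueError("stimulus sequence must be non-empty")
    if not np.all(sequence > 0):
        raise ValueError("all stimuli must be > 0")

    rng = np.random.default_rng(seed)
    measure = (
        sample_measurement_exact if mode == "exact" else simulate_measurement_path
    )
    trials: list[TrialRecord] = []
    n_degenerate = 0
    theta_prev = 0.0
    for n, stimulus in enumerate(sequence):
        m = measure(float(stimulus), params, rng)
        theta = m if n == 0 else update_threshold(m, theta_prev, params.memory_weight)
        if theta <= 0:
            n_degenerate += 1
            reproduction = None
        elif mode == "exact":
            reproduction = sample_reproduction_exact(theta, params, rng)
        else:
            reproduction = simulate_reproduction_path(
                theta, params, rng, max_time=max_time
            )
        trials.append(
            TrialRecord(
                index=n,
                stimulus=float(stimulus),
                measurement=float(m),
                threshold=float(theta),
                reproduction=reproduction,
                mode=mode,
            )
        )
        theta_prev = theta

    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} of {sequence.size} trials had a non-positive "
            "threshold (drift-dominance assumption violated); their "
            "reproductions are recorded as missing",
            DegenerateThresholdWarning,
            stacklevel=2,
        )
    return SessionResult(
        trials=trials,
        params=params,
        seed=int(seed),
        mode=mode,
        stimulus_set=stimulus_set,
    )
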