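"""Session orchestration and psychophysical summary statistics.

Turns simulated sessions into the summaries a timing/magnitude-estimation
experimenter would compute: per-stimulus means, standard deviations,
coefficients of variation and biases (regression and scalar-variability
plots), conditional biases given the previous stimulus (sequential
effects), and z-scored comparison against the analytic predictions.

An initial burn-in block (default 50 trials) is discarded from every
summary, because the closed-form predictions describe the stationary
(many-preceding-trials) limit of the reference memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytics import PredictionSet, StimulusSet
from .model import ModelParams, SessionResult, run_session

__all__ = [
    "SummaryTable",
    "SequentialTable",
    "make_stimulus_set",
    "make_sequence",
    "simulate_range",
    "summarize",
    "sequential_table",
    "compare",
]

DEFAULT_BURN_IN = 50


def make_stimulus_set(range_min: float, range_max: float, k: int = 11) -> StimulusSet:
    """``k`` evenly spaced magnitudes covering [range_min, range_max] inclusive."""
    return StimulusSet.from_range(range_min, range_max, k)


def make_sequence(
    stim_set: StimulusSet,
    n_trials: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomized presentation order: i.i.d. uniform draws with replacement."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.choice(stim_set.array, size=n_trials, replace=True)


def simulate_range(
    params: ModelParams,
    stim_set: StimulusSet,
    n_trials: int,
    seed: int = 0,
    mode: str = "exact",
) -> SessionResult:
    """Convenience wrapper: draw a randomized sequence and run the session.

    The sequence is drawn with ``seed`` and the session consumes an
    independent stream (``seed + 1``), so sequence and trial noise never
    alias.
    """
    sequence = make_sequence(stim_set, n_trials, seed=seed)
    return run_session(
        sequence, params, mode=mode, seed=seed + 1, stimulus_set=stim_set
    )


def _clean_frame(session: SessionResult, burn_in: int) -> pd.DataFrame:
    df = session.to_dataframe()
    if burn_in >= len(df):
        raise ValueError("burn_in must be smaller than the session length")
    df = df.iloc[burn_in:]
    return df[df["reproduction_ms"].notna()]


@dataclass
class SummaryTable:
    """Per-stimulus response statistics (post burn-in, missing excluded).

    ``table`` columns: stimulus_ms, n_trials, mean_reproduction_ms, sd_ms,
    cv (sd/mean), bias_ms (mean - stimulus).
    """

    table: pd.DataFrame = field(repr=False)
    burn_in_discarded: int
    n_missing_excluded: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def regression_slope(self) -> float:
        """OLS slope of mean reproduction on stimulus (1 = veridical)."""
        x = self.table["stimulus_ms"].to_numpy()
        y = self.table["mean_reproduction_ms"].to_numpy()
        return float(np.polyfit(x, y, 1)[0])


def summarize(session: SessionResult, burn_in: int = DEFAULT_BURN_IN) -> SummaryTable:
    """Group post-burn-in trials by stimulus and compute response statistics."""
    df = _clean_frame(session, burn_in)
    if session.stimulus_set is not None:
        expected = set(session.stimulus_set.values)
        present = set(df["stimulus_ms"].unique())
        missing_rows = expected - present
        if missing_rows:
            warnings.warn(
                f"no usable trials for stimuli {sorted(missing_rows)}; "
                "rows omitted",
                stacklevel=2,
            )
    grouped = df.groupby("stimulus_ms")["reproduction_ms"]
    table = pd.DataFrame(
        {
            "stimulus_ms": grouped.mean().index,
            "n_trials": grouped.size().to_numpy(),
            "mean_reproduction_ms": grouped.mean().to_numpy(),
            "sd_ms": grouped.std(ddof=1).to_numpy(),
        }
    )
    table["cv"] = table["sd_ms"] / table["mean_reproduction_ms"]
    table["bias_ms"] = table["mean_reproduction_ms"] - table["stimulus_ms"]
    n_missing = int(len(session) - burn_in - len(df))
    return SummaryTable(
        table=table.reset_index(drop=True),
        burn_in_discarded=burn_in,
        n_missing_excluded=n_missing,
    )


@dataclass
class SequentialTable:
    """Conditional biases keyed by (current stimulus, previous stimulus).

    ``slope`` is the OLS slope of trial-level bias on the previous
    stimulus' deviation from the range mean, with current-stimulus fixed
    effects (within-stimulus demeaning); its stationary expectation is
    ``a*(1-a)*A_m/A_r``.
    """

    table: pd.DataFrame = field(repr=False)
    slope: float
    slope_se: float
    burn_in_discarded: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sequential_table(
    session: SessionResult, burn_in: int = DEFAULT_BURN_IN
) -> SequentialTable:
    """Condition each trial's bias on the immediately preceding stimulus.

    The previous stimulus is taken from the raw trial order: a predecessor
    with a missing reproduction still defines the context of the next
    trial (its measurement updated the reference either way).
    """
    if len(session) < 2:
        raise ValueError("need at least two trials for sequential analysis")
    df = session.to_dataframe()
    df["prev_stimulus_ms"] = df["stimulus_ms"].shift(1)
    df = df.iloc[max(burn_in, 1):]
    df = df[df["reproduction_ms"].notna()].copy()
    df["bias_ms"] = df["reproduction_ms"] - df["stimulus_ms"]

    cells = (
        df.groupby(["stimulus_ms", "prev_stimulus_ms"])["bias_ms"]
        .agg(["size", "mean"])
        .reset_index()
        .rename(columns={"size": "n_pairs", "mean": "mean_bias_ms"})
    )

    # within-current-stimulus demeaning removes the bias component that
    # depends on T, isolating the linear effect of the previous stimulus
    y = df["bias_ms"].to_numpy().astype(float, copy=True)
    x = df["prev_stimulus_ms"].to_numpy().astype(float, copy=True)
    groups = df["stimulus_ms"].to_numpy()
    for value in np.unique(groups):
        sel = groups == value
        y[sel] -= y[sel].mean()
        x[sel] -= x[sel].mean()
    sxx = float(np.sum(x * x))
    if sxx == 0:
        slope, slope_se = 0.0, float("inf")
    else:
        slope = float(np.sum(x * y) / sxx)
        resid = y - slope * x
        dof = max(len(y) - 1 - len(np.unique(groups)), 1)
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return SequentialTable(
        table=cells, slope=slope, slope_se=slope_se, burn_in_discarded=burn_in
    )


def compare(summary: SummaryTable, predictions: PredictionSet) -> pd.DataFrame:
    """Per-stimulus z-scores of observed vs. predicted mean and variance.

    ``z_mean = (observed - predicted) / sqrt(pred_var / n)``;
    ``z_var`` uses the normal-theory standard error of a sample variance,
    ``pred_var * sqrt(2/(n-1))``.  Rows with |z| > 3 are flagged.  Being a
    stochastic check, an occasional flag at 3 SE is expected roughly once
    per ~370 rows; persistent flags across seeds indicate disagreement.
    """
    obs = summary.table
    pred = predictions.table
    if len(obs) != len(pred) or not np.allclose(
        obs["stimulus_ms"].to_numpy(), pred["stimulus_ms"].to_numpy()
    ):
        raise ValueError("summary and prediction stimulus sets do not match")
    n = obs["n_trials"].to_numpy()
    pred_mean = pred["pred_mean_ms"].to_numpy()
    pred_var = pred["pred_var_ms2"].to_numpy()
    obs_mean = obs["mean_reproduction_ms"].to_numpy()
    obs_var = obs["sd_ms"].to_numpy() ** 2
    z_mean = (obs_mean - pred_mean) / np.sqrt(pred_var / n)
    var_ratio = obs_var / pred_var
    z_var = (var_ratio - 1.0) / np.sqrt(2.0 / (n - 1))
    out = pd.DataFrame(
        {
            "stimulus_ms": obs["stimulus_ms"].to_numpy(),
            "n_trials": n,
            "observed_mean_ms": obs_mean,
            "predicted_mean_ms": pred_mean,
            "z_mean": z_mean,
            "observed_var_ms2": obs_var,
            "predicted_var_ms2": pred_var,
            "var_ratio": var_ratio,
            "z_var": z_var,
        }
    )
    out["flag_mean"] = np.abs(out["z_mean"]) > 3
    out["flag_var"] = np.abs(out["z_var"]) > 3
    return out
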