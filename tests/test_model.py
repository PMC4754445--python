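"""Unit tests for the single-trial simulators and session orchestration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from magest import (
    DegenerateThresholdError,
    DegenerateThresholdWarning,
    ModelParams,
    run_session,
    sample_measurement_exact,
    sample_reproduction_exact,
    simulate_measurement_path,
    simulate_reproduction_path,
    update_threshold,
)
from conftest import SEED


def params(**kw):
    kw.setdefault("memory_weight", 1.0)
    return ModelParams(**kw)


class TestMeasurement:
    def test_exact_moments(self):
        """Endpoint is N(A_m*T, sigma_m^2*T): sample moments at T=494 ms."""
        p = params()
        rng = np.random.default_rng(SEED)
        draws = np.array([sample_measurement_exact(494, p, rng) for _ in range(10_000)])
        se_mean = math.sqrt(494 / 10_000)
        assert abs(draws.mean() - 0.25 * 494) < 3 * se_mean
        se_var = 494 * math.sqrt(2 / 10_000)
        assert abs(draws.var(ddof=1) - 494) < 3 * se_var

    def test_zero_noise_is_deterministic_ramp(self):
        p = params(noise_measure=0.0)
        rng = np.random.default_rng(SEED)
        assert sample_measurement_exact(600, p, rng) == 0.25 * 600

    def test_rejects_nonpositive_stimulus(self):
        rng = np.random.default_rng(SEED)
        for bad in (0, -5):
            with pytest.raises(ValueError):
                sample_measurement_exact(bad, params(), rng)
            with pytest.raises(ValueError):
                simulate_measurement_path(bad, params(), rng)

    def test_exact_endpoint_distribution(self):
        """KS goodness of fit against the reference normal at T=847 ms."""
        p = params()
        rng = np.random.default_rng(SEED)
        draws = np.array([sample_measurement_exact(847, p, rng) for _ in range(10_000)])
        pval = stats.kstest(draws, "norm", args=(0.25 * 847, math.sqrt(847))).pvalue
        assert pval > 0.01

    def test_path_deterministic_ramp(self):
        p = params(noise_measure=0.0)
        rng = np.random.default_rng(SEED)
        assert simulate_measurement_path(500, p, rng) == pytest.approx(125.0, abs=1e-12)

    def test_path_partial_final_step(self):
        """The final Euler step is scaled so integrated drift covers T exactly."""
        p = params(noise_measure=0.0)
        rng = np.random.default_rng(SEED)
        assert simulate_measurement_path(7, p, rng) == pytest.approx(0.25 * 7, abs=1e-12)

    def test_path_rejects_dt_longer_than_stimulus(self):
        rng = np.random.default_rng(SEED)
        with pytest.raises(ValueError):
            simulate_measurement_path(3, params(), rng)

    def test_path_moments_match_exact_mode(self):
        p = params()
        rng = np.random.default_rng(SEED)
        draws = np.array(
            [simulate_measurement_path(494, p, rng) for _ in range(10_000)]
        )
        assert abs(draws.mean() - 123.5) < 3 * math.sqrt(494 / 10_000)
        assert abs(draws.var(ddof=1) - 494) < 3 * 494 * math.sqrt(2 / 10_000)


class TestThresholdUpdate:
    @pytest.mark.parametrize(
        "m, prev, a, expected",
        [(120, 100, 0.5, 110.0), (77.7, 123.0, 1.0, 77.7), (10, 40, 0.25, 32.5)],
    )
    def test_weighted_average(self, m, prev, a, expected):
        assert update_threshold(m, prev, a) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_rejects_weight_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            update_threshold(1.0, 1.0, bad)

    @given(
        ms=st.lists(st.floats(10, 300), min_size=2, max_size=30),
        a=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_recursion_matches_explicit_expansion(self, ms, a):
        """Iterating the recursion equals the explicit geometric-weight sum
        theta_n = a*m_n + a*sum_i (1-a)^(n-i)*m_i + (1-a)^n*m_0."""
        theta = ms[0]
        for m in ms[1:]:
            theta = update_threshold(m, theta, a)
        n = len(ms) - 1
        explicit = (
            a * ms[n]
            + a * sum((1 - a) ** (n - i) * ms[i] for i in range(1, n))
            + (1 - a) ** n * ms[0]
        )
        assert theta == pytest.approx(explicit, rel=1e-9)


class TestReproduction:
    def test_exact_moments(self):
        """First-passage time is IG with mean theta/A_r, var theta*sigma_r^2/A_r^3."""
        p = params(noise_reproduce=0.5)
        rng = np.random.default_rng(SEED)
        draws = np.array(
            [sample_reproduction_exact(100, p, rng) for _ in range(10_000)]
        )
        mu, var = 400.0, 1600.0
        lam = 100**2 / 0.5**2
        assert abs(draws.mean() - mu) < 3 * math.sqrt(var / 10_000)
        # SE of the sample variance from the known IG central moments
        sigma = math.sqrt(var)
        mu4 = (3 + 15 * mu / lam) * sigma**4
        se_var = math.sqrt((mu4 - var**2) / 10_000)
        assert abs(draws.var(ddof=1) - var) < 3 * se_var

    def test_zero_noise_reaches_threshold_on_time(self):
        p = params(noise_reproduce=0.0)
        rng = np.random.default_rng(SEED)
        assert sample_reproduction_exact(100, p, rng) == 400.0

    def test_exact_first_passage_distribution(self):
        """KS test against the reference inverse-Gaussian CDF."""
        p = params(noise_reproduce=0.5)
        rng = np.random.default_rng(SEED)
        theta = 52.9
        draws = np.array(
            [sample_reproduction_exact(theta, p, rng) for _ in range(10_000)]
        )
        mu = theta / 0.25
        lam = theta**2 / 0.25
        pval = stats.kstest(draws, "invgauss", args=(mu / lam, 0, lam)).pvalue
        assert pval > 0.01

    def test_degenerate_threshold_raises(self):
        rng = np.random.default_rng(SEED)
        for bad in (0.0, -3.0):
            with pytest.raises(DegenerateThresholdError):
                sample_reproduction_exact(bad, params(), rng)
            with pytest.raises(DegenerateThresholdError):
                simulate_reproduction_path(bad, params(), rng)

    def test_path_deterministic_with_interpolation(self):
        """With zero noise the interpolated crossing time is exact."""
        p = params(noise_reproduce=0.0)
        rng = np.random.default_rng(SEED)
        assert simulate_reproduction_path(100, p, rng) == pytest.approx(400.0, abs=1e-9)

    def test_path_mean_matches_exact_within_one_step(self):
        p = params(noise_reproduce=0.5)
        rng = np.random.default_rng(SEED)
        draws = np.array(
            [simulate_reproduction_path(100, p, rng) for _ in range(10_000)]
        )
        assert not np.any(np.equal(draws, None))
        tol = 3 * math.sqrt(1600 / 10_000) + p.dt
        assert abs(draws.astype(float).mean() - 400.0) < tol

    def test_short_time_cap_yields_missing(self):
        p = params(noise_reproduce=0.5)
        rng = np.random.default_rng(SEED)
        assert simulate_reproduction_path(100, p, rng, max_time=10) is None


class TestSession:
    def test_noiseless_full_update_is_veridical(self):
        """sigma=0, a=1, matched drifts: reproduction equals the stimulus."""
        p = params(noise_measure=0.0, noise_reproduce=0.0)
        seq = [494.0, 600.0, 700.0, 847.0]
        session = run_session(seq, p, seed=SEED)
        for t in session.trials:
            assert t.reproduction == pytest.approx(t.stimulus, abs=1e-9)

    @pytest.mark.parametrize("mode", ["exact", "path"])
    def test_replay_is_bitwise_identical(self, mode):
        p = params(memory_weight=0.6)
        seq = np.full(40, 500.0)
        a = run_session(seq, p, mode=mode, seed=SEED).to_dataframe()
        b = run_session(seq, p, mode=mode, seed=SEED).to_dataframe()
        assert a.equals(b)

    def test_threshold_recurrence_holds_exactly(self):
        p = params(memory_weight=0.37)
        rng = np.random.default_rng(SEED)
        seq = rng.uniform(494, 847, size=200)
        session = run_session(seq, p, seed=SEED)
        theta = session.trials[0].measurement
        assert session.trials[0].threshold == theta
        for t in session.trials[1:]:
            theta = p.memory_weight * t.measurement + (1 - p.memory_weight) * theta
            assert t.threshold == theta

    def test_full_update_carries_no_history(self):
        """With a=1 the threshold is just the current measurement."""
        session = run_session(
            np.linspace(494, 847, 50), params(memory_weight=1.0), seed=SEED
        )
        for t in session.trials:
            assert t.threshold == t.measurement

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            run_session([], params(), seed=SEED)

    def test_degenerate_thresholds_recorded_as_missing(self):
        """Weak drift relative to noise breaks drift dominance: the trial is
        recorded as missing, warned about, and the reference still updates."""
        p = ModelParams(
            drift_measure=0.01, noise_measure=1.0, memory_weight=1.0
        )
        seq = np.full(200, 10.0)
        with pytest.warns(DegenerateThresholdWarning):
            session = run_session(seq, p, seed=SEED)
        assert session.n_missing > 0
        for t in session.trials:
            assert t.is_missing == (t.threshold <= 0)

    def test_reference_regime_rarely_degenerate(self, reference_params, reference_set):
        """Drift dominance holds in the reference regime: <0.1% missing."""
        rng = np.random.default_rng(SEED)
        seq = rng.choice(reference_set.array, size=10_000)
        session = run_session(seq, reference_params, seed=SEED)
        assert session.n_missing / len(session) < 1e-3

    def test_csv_roundtrip(self, tmp_path):
        import json
        import pandas as pd

        p = params(memory_weight=0.8)
        session = run_session([500.0, 600.0, 700.0], p, seed=SEED)
        target = tmp_path / "session.csv"
        session.to_csv(target)
        df = pd.read_csv(target)
        assert list(df.columns) == [
            "index", "stimulus_ms", "measurement", "threshold",
            "reproduction_ms", "mode",
        ]
        assert df["threshold"].tolist() == [t.threshold for t in session.trials]
        sidecar = json.loads((tmp_path / "session.csv.json").read_text())
        assert sidecar["seed"] == SEED
        assert sidecar["params"]["memory_weight"] == 0.8
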