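import numpy as np
import pytest

from magest import ModelParams, a_min_closed_form, make_stimulus_set

# one fixed seed convention for every stochastic test
SEED = 12345


@pytest.fixture(scope="session")
def reference_set():
    """Eleven evenly spaced subsecond intervals on 494-847 ms."""
    return make_stimulus_set(494, 847, 11)


@pytest.fixture(scope="session")
def reference_params(reference_set):
    """Reference regime: A_m = A_r = 0.25, sigma_m = 1, sigma_r = 0.5,
    memory weight at the error-minimizing optimum for the range."""
    base = ModelParams(memory_weight=1.0)
    a_opt = a_min_closed_form(base, reference_set)
    return base.replace(memory_weight=a_opt)


def bootstrap_ci(values, stat, n_boot=1000, alpha=0.01, seed=SEED):
    """Percentile bootstrap confidence interval for a statistic."""
    values = np.asarray(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = np.array([stat(values[row]) for row in idx])
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
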