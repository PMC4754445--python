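# magest

A two-stage drift-diffusion model of magnitude estimation — the kind of
task where a subject experiences a stimulus magnitude (a subsecond time
interval, a distance, a loudness) and then reproduces it. The package is
aimed at computational-psychophysics researchers who want to simulate the
model, evaluate its closed-form stationary predictions, and study when and
why regression to the mean is the error-minimizing strategy.

## The model

Both processing stages are noisy integrators (drift-diffusion processes):

1. **Measurement.** While the stimulus `T` is present, an accumulator
   integrates `dm = A_m dt + σ_m dW`. Its endpoint is the internal
   measurement, `m_T ~ N(A_m T, σ_m² T)`.
2. **Reproduction.** A second accumulator `dr = A_r dt + σ_r dW` runs from
   zero until it first crosses a threshold `θ` from below; the
   first-passage time — inverse-Gaussian distributed with mean `θ/A_r` and
   variance `θ σ_r²/A_r³` — is the reproduced magnitude.

The stages are linked by an **adaptive reference memory**: the threshold is
updated every trial as an exponentially weighted average of the current
measurement and its own past,

    θ_n = a·m_n + (1−a)·θ_{n−1},   θ_0 = m_0,   0 < a ≤ 1.

In the stationary limit with randomized stimulus presentation (uniform over
a discrete set with mean `E(T)` and variance `Var(T)`), the mean
reproduction is linear in the stimulus,

    E(r|T) = a·(A_m/A_r)·T + (1−a)·(A_m/A_r)·E(T),

so the slope `a·A_m/A_r < 1` produces regression to the mean (Vierordt's
law / central tendency), the reproduction variance grows with `T` (scalar
variability), a drift mismatch `A_m/A_r ≠ 1` produces overall over- or
under-estimation, and conditioning on the previous stimulus adds a
sequential bias `a(1−a)(A_m/A_r)·(T_prev − E(T))`.

Minimizing the mean squared reproduction error
`MSE_r = E(Var(r|T)) + E(bias²)` over the memory weight gives

    a_min = 2 − sqrt( (A_m/A_r) · ( (σ_m/A_m)²·E(T)/Var(T) + 1 ) ),

linking the optimal amount of regression to the measurement Weber fraction
`σ_m/A_m` (regression effect) and to the mean-to-variance ratio of the
stimulus distribution (range effect), while `σ_r` leaves `a_min` untouched.

The package provides: stochastic simulation in exact-sampling and
Euler-path (5 ms step) modes (`magest.model`), the closed-form stationary
moments and biases (`magest.analytics`), the MSE decomposition, optimal
weight, grid-search oracle and parameter sweeps (`magest.optimality`),
experiment-level summaries and comparisons (`magest.experiment`), and a
config-driven CLI (`magest.cli`).

## Worked example

```python
from magest import (ModelParams, a_min_closed_form, make_stimulus_set,
                    mse, sequential_table, simulate_range, summarize)

stimuli = make_stimulus_set(494, 847, 11)        # ms
base = ModelParams(memory_weight=1.0)            # A_m=A_r=0.25, σ_m=1, σ_r=0.5
a_opt = a_min_closed_form(base, stimuli)
print(f"optimal memory weight a_min = {a_opt:.3f}")

params = base.replace(memory_weight=a_opt)
session = simulate_range(params, stimuli, n_trials=20_000, seed=42)
summary = summarize(session, burn_in=50)
print(summary.table[["stimulus_ms", "mean_reproduction_ms", "sd_ms", "bias_ms"]]
      .round(1).to_string(index=False))
print(f"fitted stimulus-response slope = {summary.regression_slope:.3f}")
seq = sequential_table(session, burn_in=50)
print(f"sequential-bias slope = {seq.slope:.3f}")
d = mse(params, stimuli)
print(f"RMSE at a_min = {d.total**0.5:.1f} ms")
```

prints

```
optimal memory weight a_min = 0.636
 stimulus_ms  mean_reproduction_ms  sd_ms  bias_ms
       494.0                 560.8   83.2     66.8
       529.3                 579.0   83.2     49.7
       564.6                 605.1   85.0     40.5
       599.9                 623.3   87.2     23.4
       635.2                 646.3   91.8     11.1
       670.5                 670.4   91.9     -0.1
       705.8                 690.9   94.5    -14.9
       741.1                 713.7   95.7    -27.4
       776.4                 736.6   96.0    -39.8
       811.7                 758.1   97.2    -53.6
       847.0                 780.9  101.5    -66.1
fitted stimulus-response slope = 0.628
sequential-bias slope = 0.228
RMSE at a_min = 100.5 ms
```

Short intervals are overestimated, long ones underestimated, the bias
crosses zero at the range mean (670.5 ms), the response standard deviation
grows with the stimulus, the fitted slope matches `a_min · A_m/A_r ≈ 0.636`,
and the sequential slope matches `a(1−a)·A_m/A_r ≈ 0.232`.

The same pipeline is available from the shell:

```sh
magest optimize -c config.yaml -o out/      # closed-form vs grid-search a_min
magest simulate -c config.yaml -o out/      # seeded session CSVs + manifest
magest report   -i out/                     # summary / sequential / comparison
magest sweep    -c config.yaml -o out/ --vary snr_inverse --values 1,2,4
```

where a minimal `config.yaml` is just

```yaml
ranges:
  - [494, 847]
seed: 42
```

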