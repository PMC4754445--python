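# Methods

## Model

A magnitude-estimation trial is modelled as two successive noisy
integrators. During measurement the accumulator follows
`dm = A_m dt + σ_m dW` for the duration `T` of the stimulus; its endpoint
`m_T ~ N(A_m T, σ_m² T)` is the internal estimate. During reproduction a
second accumulator `dr = A_r dt + σ_r dW` starts at zero and runs until it
first crosses a threshold `θ > 0` from below; with a single absorbing bound
the first-passage time is inverse Gaussian,
`r ~ IG(μ = θ/A_r, λ = θ²/σ_r²)`, with mean `θ/A_r` and variance
`θσ_r²/A_r³`. The threshold is an adaptive reference memory updated every
trial, `θ_n = a·m_n + (1−a)·θ_{n−1}` with `θ_0 = m_0`. Unrolling the
recursion shows `θ_n` is an exponentially weighted average of all past
measurements; `a = 0` is excluded because it would freeze the reference at
the first measurement forever.

All times are in ms, drifts in accumulator units per ms, noise amplitudes
per √ms; accumulator units are dimensionless.

### Stationary predictions

For randomized presentation (i.i.d. uniform draws from a discrete stimulus
set) and after the reference has equilibrated, the geometric series in the
unrolled recursion gives closed forms for the threshold mean and variance,
and the laws of total expectation/variance propagate them through the
reproduction stage (`magest.analytics`). Because the preceding stimuli are
independent of the current one, these conditional-moment formulas are exact
in the stationary limit; the only approximation in using them on simulated
sessions is the finite burn-in (below) and Monte-Carlo error. The
stimulus-set moments `E(T)`, `Var(T)` are population moments of the
discrete set under uniform weighting, not sample moments of a realized
sequence, so predictions do not depend on the particular presentation
order.

### Error minimization

The mean squared reproduction error splits into
`MSE_r = E(Var(r|T)) + E(bias(T)²)`. The variance term is the expected
within-stimulus variability (the quantity a subject plausibly minimizes,
rather than the total variance, which would also count the deliberate
spread of responses across stimuli). The bias-squared term is assembled by
numerically averaging the squared per-stimulus bias over the stimulus set —
exact for a discrete set and immune to algebraic slips; the equivalent
closed form

    E(bias²) = (1 − a·A_m/A_r)²·Var(T) + (1 − A_m/A_r)²·E(T)²

is exposed separately (`mean_squared_bias_closed_form`) and the two routes
are asserted equal in the tests.

Setting `d(MSE_r)/da = 0` and simplifying (the polynomial
`a(2−a)² + (1−a)(a²−3a+1)` in the numerator collapses to 1) yields

    (2 − a_min)² = (A_m/A_r)·((σ_m/A_m)²·E(T)/Var(T) + 1)
    a_min = 2 − sqrt((A_m/A_r)·((σ_m/A_m)²·E(T)/Var(T) + 1))

A brute-force grid search over `a ∈ (0, 1]` of the assembled MSE serves as
an independent oracle: the tests require agreement within one grid step
(10⁻³) over random parameter tuples and a vanishing central-difference
derivative at the optimum. Stationary points outside `(0, 1]` are reported
unclamped, flagged infeasible, and the grid-search best-in-range is used
instead; the boundary of feasibility (`a_min → 0`) lies at
`(A_m/A_r)·((σ_m/A_m)²·E/Var + 1) = 4`.

## Parameters and defaults

| parameter | symbol | default | units | role |
|---|---|---|---|---|
| `drift_measure` | A_m | 0.25 | 1/ms | measurement ramp rate |
| `noise_measure` | σ_m | 1.0 | 1/√ms | measurement diffusion |
| `drift_reproduce` | A_r | 0.25 | 1/ms | reproduction ramp rate |
| `noise_reproduce` | σ_r | 0.5 | 1/√ms | reproduction diffusion |
| `memory_weight` | a | required (config: optimal) | — | reference update weight, (0, 1] |
| `dt` | Δt | 5 | ms | Euler step, path mode |

The default drifts and noise amplitudes are the reference subsecond-timing
regime used throughout the tests; `σ_m/A_m = 4 √ms` plays the role of the
Weber fraction. When a config omits `memory_weight`, it resolves per range
to the error-minimizing weight. The derived quantities exposed on
`ModelParams` are the drift ratio `A_m/A_r` and inverse SNR `σ_m/A_m`.

Stimulus ranges default to eleven evenly spaced values including both
endpoints. The reference range is 494–847 ms; the range-effect analyses add
671–1023 and 847–1200 ms — three equal-width ranges of increasing mean, for
which the optimal weights come out as 0.636, 0.553 and 0.479 (stronger
regression for higher mean-to-variance ratio).

## Synthetic sessions: what they emulate, what they do not

`make_sequence` emulates randomized presentation: i.i.d. uniform draws with
replacement from the discrete set, exactly the sampling regime under which
the stationary formulas are derived. Real experiments often constrain runs
(no immediate repeats, balanced blocks), have finite inter-trial dynamics,
attention lapses, motor delays and non-stationary strategies; none of these
are modelled. Passing tests therefore show internal consistency of
simulation and theory under the model's own assumptions — not that the
model fits any particular human dataset (no fitting to empirical data is
included, by design).

Sessions default to 10,000 trials per stimulus for the quantitative
concordance checks (standard errors of per-stimulus means ≈ 1 ms) and
1,000 trials per stimulus for the coarse empirical-MSE bracketing of the
optimal weight; smaller sizes are used where only a direction or identity
is asserted.

## Numerical choices

* **Exact mode** draws measurement endpoints from the Gaussian law and
  reproduction times via `numpy`'s Wald (inverse-Gaussian) sampler with
  `λ = θ²/σ_r²`; with zero noise both collapse to their deterministic
  limits.
* **Path mode** uses Euler–Maruyama with Δt = 5 ms. The measurement stage
  scales the final partial step so the integrated time is exactly `T`
  (stimuli need not be multiples of Δt); for constant drift and additive
  noise the scheme is distribution-exact, so path and exact modes differ
  only by Monte-Carlo error. The reproduction stage checks the threshold at
  every step and linearly interpolates the crossing time between the last
  sub-threshold and first supra-threshold point, removing the O(Δt)
  positive bias; a residual first-passage discretization bias of order
  σ_r√Δt remains, hence the one-Δt tolerance in the path-vs-exact tests.
  Reproduction integration is capped at `10·θ/A_r` (generous in the
  drift-dominated regime); hitting the cap yields a missing response.
* **Degenerate thresholds.** The model assumes drift dominance
  (`A·T ≫ σ√T`), under which thresholds are positive. If a threshold comes
  out ≤ 0 it cannot be crossed from below: the trial's reproduction is
  recorded as missing, a warning is emitted, the trial counts into
  `n_missing`, and the reference is still updated with the measurement —
  never silently clamped — so violations of the assumption remain
  observable. In the reference regime the missing fraction is far below
  0.1%.
* **Randomness.** One seeded `numpy` generator per session, consumed in
  trial order (measurement draw, then reproduction draw), makes sessions
  bit-reproducible; sequence generation uses a separate stream so stimulus
  order and trial noise never alias.
* **Burn-in.** The stationary formulas hold for `n → ∞`; the reference's
  memory decays as `(1−a)ⁿ`, so 50 trials reduce the transient below
  machine precision for any `a ≥ 0.3`. All summaries discard a 50-trial
  burn-in by default; tests verify burn-in 50 vs 200 changes nothing beyond
  Monte-Carlo error.
* **Grid search** evaluates `a ∈ {step, 2·step, …, ≤1}` with ties broken
  toward smaller `a`; the step is capped at 0.1 and defaults to 10⁻³ for
  oracle comparisons, well below any tolerance asserted.
* **Sequential slope estimation** regresses trial-level bias on
  `T_prev − E(T)` with current-stimulus fixed effects (within-stimulus
  demeaning of both variables). This matches the additive linear form of
  the conditional-bias prediction and removes the current-stimulus bias
  component exactly; the reported standard error is the usual OLS one with
  degrees of freedom reduced by the number of fixed effects.
* **Statistical tolerances in tests.** Stochastic checks use 3 standard
  errors or percentile-bootstrap 99% intervals at fixed seeds. Where many
  cells are checked simultaneously (11 stimuli × several statistics), a
  single ~3 SE excursion is expected by chance in a few percent of seeds;
  such a cell is re-checked once on an independent replication session with
  a fixed second seed and must pass there. A systematic discrepancy would
  fail both stages.

## Design choices where the design was open

* **Discretization `k = 11`** values per range: printed ranges specify
  endpoints, not a grid; eleven evenly spaced values follows the classic
  subsecond interval-reproduction design and is configurable everywhere.
* **Sweep axes.** Varying the drift ratio changes `A_r` with `A_m, σ_m`
  held fixed, so the measurement SNR is untouched and the ratio's effect is
  isolated. Varying the dispersion ratio `E/Var` rebuilds a symmetric
  two-point stimulus set with the same mean and the requested variance —
  the only two-parameter family realizing arbitrary (mean, variance)
  exactly.
* **Infeasible optima** are reported rather than raised: the closed form is
  returned unclamped together with a feasibility flag and the grid-search
  best within `(0, 1]`.
* **Missing-response bookkeeping.** Missing trials are excluded from
  summaries, but a missing trial's stimulus still defines the "previous
  stimulus" of its successor, since its measurement updated the reference.

## Known limitations

* No lower (reflecting or absorbing) bound on either integrator: outside
  the drift-dominated regime the model produces missing responses rather
  than a modified first-passage law.
* Thresholds are constant within a trial; no collapsing bounds, no
  non-Gaussian noise.
* The standard deviation of reproductions grows sub-linearly (√T-law
  dominated) in the stimulus; a strictly linear Weber law would require
  extensions (e.g. stimulus-dependent drift ratio) that are out of scope.
* Only the first two moments of the reproduction distribution under a
  random threshold are available in closed form; the full density has no
  general solution and is accessible by simulation only.
* The memory weight is fixed within a session; no online adaptation of `a`.
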