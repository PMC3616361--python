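# Methods

## Model

`oncoaddict` simulates the response of an oncogene-addicted tumor to MYC
inactivation as a population of cells distributed over six states:

| state | meaning |
|-------|---------|
| M | MYC transcriptionally active |
| N | MYC off, still under tetracycline (dox) control |
| A | irreversibly committed to apoptosis, not yet dead |
| D | differentiated / dormant quasi-normal cells |
| S | oncogene-inactivation-induced senescence (OIIS), absorbing |
| E | escaped conditional MYC control (tTA mutation, MYC-downstream pathway activation) |

Transitions are first-order with rate constants K (day⁻¹):

- M: apoptosis commitment `k_M_apop`; proliferation `k_M_prolif` (birth);
  M→N at `k_inactivation`, open only while the MYC program is **off**.
- N: apoptosis `k_N_apop`, differentiation `k_diff`, senescence `k_senesc`,
  escape `k_relapse`; proliferation `k_N_prolif` (birth); N→M at
  `k_activation`, open only while the program is **on**. The M↔N path is
  never open in both directions at once (non-instantaneous, dox-dependent
  switching).
- D: apoptosis `k_D_apop` (tumor-type dependent); reawakening D→M at
  `k_wake`, open only while the program is **on** (dormant cells regain
  neoplastic behavior upon MYC reactivation, not spontaneously).
- E: apoptosis `k_E_apop`; proliferation `k_E_prolif` (birth). Escaped
  cells ignore the dox program.
- S: absorbing (irreversible arrest). A: leaves only through delayed death.

The MYC program is a piecewise-constant on/off schedule (the experimentally
controlled ±dox variable), evaluated left-closed: a switch takes effect at
exactly its switch time.

Immune effects enter implicitly through rates: immunocompetent hosts have
`k_relapse = 0`; immunodeficient hosts have `k_relapse = 3e-8` day⁻¹ and —
because OIIS requires intact host immunity (CD4⁺ T cells) — `k_senesc = 0`.
The senescence gating is an interpretive choice of this package (the base
rate table splits only `k_relapse` by immune status) and can be overridden.

Default rate table (day⁻¹): `k_M_prolif = k_E_prolif = 0.5`,
`k_M_apop = 0.05`, `k_N_prolif = 0.1`, `k_N_apop = 2`, `k_diff = 0.02`,
`k_senesc = 0.001`, `k_wake = 0.1`, `k_E_apop = 0.01`,
`k_D_apop = 0.05 / 0.002 / 0.01` (lymphoma / osteosarcoma / hepatocellular),
`k_inactivation = k_activation = 2`.

## Commitment-to-death delay

Apoptosis is modeled in two stages: commitment (a kernel transition into A)
and death (removal from the system) a fixed `tau_apop` days later. Cells in
A still emit bioluminescence, which is why tumor signal plateaus for several
days after inactivation before collapsing. In vivo, proliferative arrest is
essentially immediate while visible apoptosis lags by roughly 4–5 days;
`tau_apop` has no independently measured value, so its default of **4.5 d**
is a calibration to that observation, not a measured constant.

Mechanically the delay is a FIFO of integer cohorts keyed to the grid: a
cohort committed during the step starting at `t` is stamped
`death_time = t + tau_apop` and removed in the step where
`death_time ≤ t_step + dt` (grid index `m + max(K, 1)` for commitment step
`m`, `K = tau_apop/dt`). The mean-field engine uses a ring buffer of
commitment fluxes with identical indexing, so the two engines agree in
expectation exactly, not merely in the continuum limit. Commitment fluxes
before t = 0 are zero; a pre-existing A count in the initial condition is
treated as committing at t = 0.

## Integration scheme

Both engines advance on a fixed Euler grid, `dt = 0.02` d, small relative to
the fastest rate (2 day⁻¹ → per-step probability 0.04). Per-step transition
probability is first-order, `p = K·dt` (at these magnitudes it differs from
`1 − exp(−K·dt)` by < 0.1% per step). The stochastic engine draws one
multinomial per source state per step — exits are mutually exclusive and can
never oversubscribe the state count — and one binomial per proliferating
state for births. Order of operations: transitions from start-of-step
counts, then births, then matured deaths; daughters born in a step cannot
transition until the next step. No Gillespie/SSA variant is provided: the
fixed-step scheme is itself part of the model being studied.

Numerical notes:

- First-order Euler carries a global discretization bias of about
  `r²·t·dt/2` against the continuous-time solution (≈2% for a net rate of
  0.45 day⁻¹ over 10 days at dt = 0.02). The *stochastic* expectation equals
  the *discrete* deterministic recursion exactly, so engine cross-checks are
  exact while analytic-exponential comparisons inherit this bias; tests
  compare against `(I + Q·dt)^n` closed forms exactly and against
  `exp(Q·t)`/analytic forms at the theory-bound tolerance.
- Negative values from Euler undershoot are clamped to zero with a warning;
  under the default table at dt = 0.02 this never triggers (asserted).
- `tau_apop` is snapped to the nearest grid multiple (with a warning when
  material); `t_end` is rounded up to the grid.
- Stochastic counts are int64. Because escaped-cell growth is unbounded
  (the model has no carrying capacity), long post-relapse horizons can
  exceed the safe integer range; `simulate(..., stop_above=...)` truncates a
  run once the signal reaches a ceiling. The sensitivity sweep stops runs at
  2× the deterministic pre-inactivation peak, far above the relapse
  threshold it measures.

## Reproducibility

Every stochastic run is a pure function of its inputs and one integer seed
(numpy PCG64). Ensembles derive per-run seeds as the first `n_runs` 32-bit
words of `SeedSequence(base_seed)` masked to 31 bits — prefix-stable, so run
*i* is unchanged when the ensemble grows, and independent of replicate
order. Run records (config snapshot, package version, seeds) plus the
package version regenerate every CSV byte-exactly; CSV floats use Python's
shortest round-trip representation.

## Scenarios and summary metrics

All presets grow 10⁶ MYC-on cells for 10 days (a scale and growth phase
chosen here; measured tumor sizes are not part of the model), then switch
MYC off:

- `fig4` — immunocompetent lymphoma, `tau_apop = 0` (no-delay ablation), 30 d.
- `fig5` — immunocompetent lymphoma, default delay (sustained regression), 30 d.
- `fig6` — immunodeficient lymphoma, single run (regression then relapse), 70 d.
- `fig7` — as fig6 with 20 replicates (relapse-variability ensemble), 70 d.

Horizons are chosen so each behavior completes: under the default deficient
table the first escape occurs within days of inactivation and the escaped
clone (net growth 0.49 day⁻¹) re-crosses half the pre-inactivation peak
near day 50.

Metrics on the BLI-proxy signal (default: sum of all six states, since
apoptosis-committed cells still emit; the included states are
configurable):

- **onset_of_decline**: first time after inactivation at which the signal
  falls below 99% of its value at the switch and stays below for 1 day
  (persistence guards against stochastic dips); both thresholds
  configurable. Note the signal *overshoots* (~30%) after the switch — M
  cells keep proliferating at 0.5 day⁻¹ while converting to N at 2 day⁻¹ —
  so the measured onset (~5 d in `fig5`) is the death-onset lag of ~4.5 d
  plus the time to shed the overshoot.
- **regression_half_time**: time after the switch for the signal to halve
  relative to its value at the switch. The regression statistic has no
  canonical definition; this operational choice is reported with results.
- **relapse_time**: first time after the post-switch nadir at which the
  signal re-crosses 50% (configurable) of the pre-inactivation peak; absent
  when the tumor never regressed below or never re-crossed the threshold.
- **variability report**: coefficients of variation (sample SD/mean) of
  regression half-time and relapse time across replicates, computed only
  over runs where the metric is defined (counts reported). The model's
  signature asymmetry: regression CVs are ~10⁻¹⁶–10⁻³ while relapse CVs are
  ~0.04–0.06, because regression is a law-of-large-numbers collapse of ~10⁸
  cells while relapse hinges on the timing of a handful of rare escape
  events (expected escapes per run ≈ `k_relapse · ∫N dt` ≈ 1.4) amplified
  by exponential regrowth.
- **relapse_rate_sensitivity**: median relapse time over replicates per
  (`k_relapse`, `k_E_prolif`) grid cell. A 10× increase in the mutation
  rate advances the median by only ~`ln(10)/(k_E_prolif − k_E_apop)` ≈ 5 d,
  while doubling the escape growth rate halves the regrowth time (~18 d
  advance): relapse kinetics are dominated by the escaped clone's growth
  rate, not the mutation supply.

## What the generator does and does not emulate

Synthetic scenarios reproduce the *kinetic structure* of conditional-MYC
mouse experiments: growth, inactivation, delayed apoptotic collapse,
immune-dependent sustained regression vs relapse, and replicate-to-replicate
relapse variability. They do not model doxycycline pharmacokinetics (the
program is binary), explicit immune effector populations, angiogenesis,
spatial structure, imaging physics, or measurement noise — so passing tests
demonstrate internal consistency and the emergent behaviors above, not
quantitative agreement with any specific animal's imaging series.

## Known limitations

- Rates are linear (no density dependence): regrown tumors increase without
  bound, hence the truncation ceiling described above.
- The deterministic engine treats compartments as continuous masses; it
  relapses deterministically via fractional escaped cells, which is exactly
  the artifact the stochastic engine exists to correct.
- Immune state is binary (competent/deficient); intermediate immune
  function can only be expressed by overriding `k_senesc`/`k_relapse`
  manually.
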