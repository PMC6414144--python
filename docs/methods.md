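# Methods

## Model

The simulator couples three deterministic ingredients:

1. **Gompertz growth.** `dT/dt = a·T − b·T·ln(T/T_ref)` with `a, b` in
   1/day and volumes in cm³. The closed form
   `T(t) = T_ref·exp(a/b + (ln(T0/T_ref) − a/b)·e^(−b·t))` is implemented
   alongside the numerical path and is used as an oracle in the tests.
2. **Three compartments.** Dividing cells `T_A` carry the Gompertz term;
   quiescent cells `T_Q` and non-dividing cells `T_D` do not proliferate.
   First-order rates `P12, P21, P13, P23` (1/day) exchange volume between
   the pools and `η` clears `T_D`. The transition terms conserve total
   volume exactly (checked by a dedicated conservation test with growth
   and clearance switched off).
3. **Linear–quadratic kill.** A fraction of dose `D` rescales `T_A` and
   `T_Q` by `exp(−(α·D + β·D²))` with compartment-specific `(α, β)`.
   Killed volume leaves the system by default; an optional `kill_to_td`
   flag routes it into `T_D` instead, making shrinkage clearance-limited.
   Non-dividing cells receive no kill term — they are already doomed.

### Conventions the equations leave open

* **Logarithm argument.** `ln(T)` on a dimensional volume is resolved by a
  reference volume `T_ref` (default 1 cm³). The ODE's fixed point is then
  `T_ref·e^(a/b)`; the alternative capacity convention `T0·e^(a/b)` is
  recovered by setting `T_ref = T0`. `carrying_capacity` exposes both and
  asserts neither as canonical.
* **Rates, not probabilities.** The `P_ij` are used as continuous-time
  rate coefficients (1/day) in the ODE, which is the only reading
  consistent with their appearance in a differential equation.
* **The factor 2 in the kill rate.** The rate form
  `−(α·D + 2β·D²)·T` is read as the dose-derivative of the L–Q
  log-survival `α·D + β·D²` (d/dD = α + 2β·D): delivering a fraction of
  dose `D` therefore yields survival `exp(−(α·D + β·D²))`. The default
  course simulator applies this instantaneously, appropriate when beam-on
  time (minutes) is negligible against the daily gap.
  `finite_duration_fraction` keeps the literal rate form: dose accumulates
  at `D/duration` and the instantaneous log-kill rate is
  `(α + 2β·D_cum)·Ḋ`, which integrates to the same survival when growth is
  frozen — the two modes are exactly consistent in that limit (tested).
* **Transposed source term.** The treated `T_A` equation uses `P21·T_Q`
  as its quiescent source, matching the untreated system's mass balance.

## Parameters

| parameter | units | default / packaged value | meaning |
|---|---|---|---|
| `a` | 1/day | 0.56 / 0.653 (breast GM / 3-C); 0.742 / 0.837 (lung) | growth coefficient |
| `b` | 1/day | 0.0719 (breast); 0.0792 / 0.081 (lung) | log damping |
| `T_ref` | cm³ | 1 | log reference volume |
| `P12, P21` | 1/day | 0.1 | dividing ↔ quiescent exchange |
| `P13, P23` | 1/day | 0.05 | flow into the non-dividing pool |
| `η` | 1/day | 0.2 | clearance of non-dividing cells |
| `β1, β2` | 1/Gy² | 0.035 | quadratic L–Q coefficients |
| `α1, α2` | 1/Gy | ratio × β | linear L–Q coefficients |
| control threshold | — | 0.05 | viable fraction defining control |
| `dt_out` | day | 0.1 | output sampling step |

The published settings behind the experiment presets quote only the
ratios `α/β`; the packaged presets pin the absolute scale with
`β = 0.035 Gy⁻²` — a mid-range value for solid tumors — so ratio 10 gives
`α = 0.35 Gy⁻¹`. Initial compartment volumes are never derived from a
total: every run states them explicitly. The treatment presets start from
`T_A = 500, T_Q = 200, T_D = 0 cm³` (the quiescent-volume study replaces
`T_Q` by its swept value over a 500 cm³ dividing seed); the untreated
growth comparison starts both models from a 1 cm³ dividing seed. These
fill-ins are documented in the preset files themselves.

## Numerics

* **Integrator.** `scipy.integrate.solve_ivp` with the embedded
  Runge–Kutta RK45 pair, `rtol = 1e-8`, `atol = 1e-10 cm³` (configurable).
  RK45 was chosen over higher-order pairs because output is read through
  the dense interpolant at fixed sample times, and RK45's interpolant at
  this tolerance tracks the analytic Gompertz solution to better than
  1e-7 relative over 100 days, comfortably inside the 1e-6 target; very
  high-order pairs take steps so large that interpolation, not
  integration, dominates the error budget.
* **Eradication floor.** `ln T → −∞` as `T → 0`, so the Gompertz term is
  defined as exactly 0 for `T_A ≤ 1e-12 cm³`. Such states are treated as
  eradicated; because the growth term vanishes there, an eradicated
  viable pool can never regrow (tested). Note the model's per-capita
  growth rate `a − b·ln T` grows as volume shrinks toward the floor — a
  known pathology of the Gompertz law at near-cure volumes, which the
  floor bounds but does not remove.
* **Negative excursions.** The right-hand side evaluates on the
  non-negative part of the state; sampled values below zero by less than
  1e-7 cm³ (solver round-off) are clamped to zero, anything more negative
  raises `IntegrationError`. Solver failure or non-finite output raises
  rather than returning NaN.
* **Course structure.** `run_course` anchors a global sampling grid at
  course start, integrates each inter-fraction gap adaptively, and records
  the state immediately before and after each fraction (two rows at the
  same time — trajectory times are non-decreasing, not strictly
  increasing, exactly at these events). The course end used by the
  experiment metrics is the time of the last fraction, i.e. the
  post-fraction state with no extra regrowth tail; a longer `t_end`
  appends an untreated tail.
* **Time to control** is the first sampled state at or below
  `threshold × baseline` (inclusive, no interpolation); at the default
  `dt_out = 0.1 day` the discretization error is negligible against the
  daily fraction spacing.

## Experiment conventions

* **Dose sweep** supports a fixed fraction count (the 30-fraction setting)
  and a fixed total dose (the 36 Gy comparison, where 1.2 Gy × 30 and
  3.0 Gy × 12 are contrasted). Fractions are daily with no weekend gaps.
* **Quiescent-volume sweep.** All runs share one underlying tumor and
  differ only in the quiescent load added to it, so the sweep normalizes
  every run by the *common* base initial viable volume rather than each
  run's own (larger) baseline. This matches comparing absolute volume
  curves on a single axis, which is how the study is framed; per-run
  normalization would penalize the added load for not bringing its own
  growth engine and can invert the ordering.
* **Radiosensitivity sweep.** The `α/β` ratio is swept at *fixed β*, with
  α carrying the ratio — the documented convention (the alternative,
  fixing α and varying β, changes the quadratic term instead). Under it,
  a larger quiescent-cell α means more kill per fraction and a smaller
  end-of-course volume. An `alpha` mode accepts absolute α values
  directly, including the β = 0 pure-exponential limit.

## Validation problem sizes

The test suite validates against: the analytic Gompertz solution over
100–200 days; an independent fixed-step classical RK4 oracle at
`h = 1e-3 day` (written directly from the equations, not shared with the
implementation) over 25-day growth runs on all four packaged parameter
sets and over a full 12-fraction course; exact survival algebra with
growth frozen; and property checks (non-negativity, conservation, dose
monotonicity, reduction of the 3-C model to two-compartment and pure
Gompertz limits). These horizons keep the full suite under ten seconds
while covering the growth curve from exponential phase to saturation.

## Limitations

* No normal-tissue complication model: the simulator scores tumor control
  only, so schedule comparisons ignore toxicity limits on fraction size.
* No dose-rate or repair kinetics beyond the finite-duration window; no
  cell-cycle redistribution or reoxygenation between fractions.
* No spatial structure, vasculature or oxygenation; compartments are
  well-mixed volumes.
* Parameters are illustrative literature-scale values, not fits to
  clinical data; absolute α and β in the presets are a documented
  convention, so simulated volumes should be read comparatively, not as
  patient-level predictions.
* The model is deterministic; it cannot represent stochastic extinction
  of the last surviving clonogens — "control" is a threshold on a
  continuous volume, not a cure probability.
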