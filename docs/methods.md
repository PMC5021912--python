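# Methods

## The model

`bilung` simulates a bi-level positive airway pressure (BIPAP) ventilator
driving **two** lungs through a common pressure node. Single-compartment
ventilation models cannot represent how gas delivery is shared between
two lungs with unequal mechanics; this package models exactly that
coupling, at the fidelity of a bench test-lung rig:

- **Ventilator** — an ideal pressure source following a trapezoid
  setpoint: linear ramp from EPAP to IPAP over the rise time `Tr`,
  plateau at IPAP until the inspiratory time `Ti`, step release to EPAP
  for the rest of the cycle (period `60/BPM` s). No source impedance, no
  triggering, no leak.
- **Airways** — each lung connects to the source node through one
  *equivalent throttle*: a lumped orifice of diameter `d` (mm) standing
  in for the airway/tube resistance. Mass flow follows the compressible
  orifice law with the subsonic branch

  `q = Ae · p_up · √(1/θ) · √( 2k/(k−1) · 1/R · ((p_d/p_u)^{2/k} − (p_d/p_u)^{(k+1)/k}) )`

  and the choked branch (the same expression frozen at the critical
  ratio `b = (2/(k+1))^{k/(k−1)}`, ≈ 0.528 for air) when
  `p_d/p_u ≤ b`. Flow is signed by the pressure gradient, so one
  throttle carries both inspiration and expiration. At clinical BIPAP
  pressures (a few kPa of gauge swing on top of 1 atm) the pressure
  ratio stays around 0.98 — far above `b` — and the flow is always
  subsonic; an acceptance test verifies this rather than assuming it.
- **Lungs** — isothermal ideal-gas containers with linear compliance
  `C = dV/dp`. Differentiating `pV = mRθ` and eliminating `dV` through
  the compliance gives, per lung,

  `dp/dt = Rθ q V / (V² + C m Rθ)`, `dV/dt = C dp/dt`, `dm/dt = q`.

  The three states are integrated redundantly; `pV = mRθ` is then an
  exact invariant whose numerical drift (the *ideal-gas residual*)
  directly measures integrator error. It stays below 1e−6 relative at
  the default tolerances (tested).

### Assumptions

No leaks; quasi-balanced (isothermal) gas states; constant linear
compliance per scenario; tube/tract compliance neglected (justified at
2–40 cmH2O working pressures); airway resistance lumped into a fixed
orifice (no time-varying resistance, no inertance); the same absolute
temperature θ in the flow law and the gas law.

## Parameters, units, defaults

Internal computation is entirely SI (Pa absolute, m³, kg, s, K). Clinical
units appear only in configuration and reports: 1 cmH2O = 98.0665 Pa,
atmosphere = 101325 Pa.

| parameter | meaning | default | why |
|---|---|---|---|
| IPAP / EPAP | inspiratory / expiratory pressure level (cmH2O gauge) | 22 / 4 | reference bench setting |
| BPM | breaths per minute | 20 | reference bench setting |
| Ti / Tr | inspiratory time / pressure rise time (s) | 1.0 / 0.3 | reference bench setting |
| C | respiratory compliance (mL/cmH2O) | 10 per lung | reference bench setting |
| d | equivalent throttle inlet diameter (mm) | 3.2 per lung | reference bench setting |
| Cd | discharge coefficient | 1.0 | no value is published for the rig; the quoted d is taken as fully effective; exposed for calibration |
| V0 | initial lung gas volume (L) | 1.5 | unstated for the rig; a plausible adult test-lung scale. V0 only sets the compressibility term `V²` against the compliance term `C·m·Rθ` in the pressure-rate denominator (≈ 0.15 : 1 at defaults), so tidal metrics are insensitive to it |
| θ | gas temperature (K) | 293.15 | room-temperature bench; isothermal |
| R, k | specific gas constant, heat-capacity ratio | 287.05 J/(kg·K), 1.4 | dry air |
| p_start | initial lung gauge pressure (cmH2O) | EPAP | expiratory baseline; warm-up removes any residual transient |

Integration defaults: LSODA with `rel_tol` 1e−8, `abs_tol` 1e−10,
`max_step` min(0.01 s, Tr/10), restarted at every waveform breakpoint
{0, Tr, Ti} of every cycle so no adaptive step crosses a derivative
discontinuity; 5 warm-up + 3 recorded cycles on a 1 ms output grid.
Steadiness is declared when per-cycle volume excursions of both lungs
change by < 1e−4 relative between the last two warm-up cycles (the
reference scenario settles in 2–3 cycles). Halving all tolerances moves
tidal volumes by far less than 0.1% (tested).

## Numerical choices

- **Breakpoint-exact stepping.** The setpoint is piecewise smooth; the
  integrator is restarted at each breakpoint and evaluation points are
  clipped into each sub-interval to guard against float rounding between
  the uniform grid and the breakpoint times.
- **Square-root touchdown.** Near pressure equalisation the orifice law
  behaves like `q ∝ √Δp`, which is non-Lipschitz at Δp = 0: each lung
  reaches the setpoint in *finite* time and then sits at equilibrium.
  LSODA handles this robustly but leaves ±2e−7 kg/s of chatter around
  the equilibrium. Consequences: (a) the flow-ratio mask (floor
  1e−7 kg/s) flickers during equilibrated phase tails, so the masked
  fraction of a cycle is noise-determined — with exact arithmetic about
  a third of the reference cycle has identically zero total flow and
  would be masked; (b) the sign-structure of flows per phase holds up to
  this chatter amplitude.
- **Hot-path RHS.** `simulate` uses a scalar-arithmetic closure of the
  right-hand side, algebraically identical to the public
  `system_derivatives` composition (pinned to ≤1e−12 relative agreement
  by a test); this is ~12× faster inside the solver.
- **Tidal volume** is the per-cycle volume excursion (max − min of V),
  which equals the integral of inspiratory volumetric flow for a
  periodic cycle. The right-lung share is `VT_r/(VT_r+VT_l)`; a breath
  that moves no gas is flagged degenerate rather than given a share.
- **Flow-ratio masking, not clamping.** `q_r/q_s` is undefined where
  `|q_s| ≤ eps` (default 1e−7 kg/s ≈ 0.005 L/min) and reported raw
  elsewhere — values outside [0, 1] are physical (transient inter-lung
  redistribution when the two time constants differ) and are preserved.
- **Determinism.** The model has no stochastic element; re-running any
  scenario or sweep is bit-identical, and swapping the two lung
  parameter blocks relabels the trajectory bit-for-bit (tested).

## The sweep suite

Seven one-at-a-time families perturb the symmetric reference bench:
right-lung compliance (5–30 mL/cmH2O every 5), right throttle diameter
(1.6–4.0 mm every 0.4 — the published range gives no step; 0.4 mm keeps
the printed endpoints and the 3.2 mm base on the grid), IPAP {18, 22,
24}, EPAP {4, 6, 8} cmH2O, BPM {20, 25, 30}, Ti {1.0, 1.2, 1.4} s, Tr
{0.2, 0.3, 0.4} s. The coarse grids used for the instantaneous
flow-ratio studies of C and d ({8, 12, 14} mL/cmH2O and {2.0, 2.8,
4.0} mm) are exposed separately as `FLOW_RATIO_GRIDS`.

Expected physics, all covered by tests: equal lungs split flow exactly
50/50; raising the right lung's C or d strictly raises its tidal-volume
share (monotone over both grids); a share crosses 0.5 exactly where the
perturbed parameter crosses the reference value; mirror scenarios have
shares summing to 1.

## What a green suite does and does not establish

The simulator reproduces the *model's* closed-form limits (quasi-static
`VT → C·(IPAP−EPAP)`, 180 mL at defaults, within 2%), its conservation
structure (gas-law residual, per-cycle mass closure < 0.5% of inspired
mass, `q_s = q_r + q_l` exact), and the published ordering/symmetry
claims. It does not validate the model against measured waveforms: no
tabulated experimental data exist for the bench, and hardware effects
(source impedance, exhalation-valve dynamics, leaks, humidity, nonlinear
compliance) are outside the model. Share values for extreme parameter
combinations where both lungs fully equilibrate every breath (e.g. large
d on both sides) differ by only ~1e−6–1e−3 and are physically
near-degenerate even though the strict ordering still holds.

## Known limitations

- No patient effort, triggering, or leak model; expiration passes
  backwards through the inspiratory throttle rather than a separate
  exhalation-valve model.
- Linear compliance only; no inertance; no time-varying resistance.
- The fall from IPAP to EPAP is a step; real ventilators have a finite
  release profile.
- Flow-ratio values inside equilibrated phase tails are dominated by
  solver chatter at the 1e−7 kg/s level; treat masked/near-floor samples
  accordingly.
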