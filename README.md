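# bilung

A simulator for **bi-level positive airway pressure (BIPAP) ventilation
of two coupled lungs**. Most ventilation models treat the patient as a
single compartment; real patients have two lungs with different
mechanics, and the gas delivered each breath is shared between them.
`bilung` models that sharing: a BIPAP ventilator (an ideal pressure
source following a trapezoid IPAP/EPAP waveform) drives two lungs
through equivalent orifice throttles, and each lung evolves as an
isothermal ideal-gas container with linear compliance.

It is intended for respiratory-mechanics and ventilator-bench studies:
exploring how the flow split `q_r/q_s` and the tidal-volume share
`VT_r/VT_s` respond to lung and ventilator parameters.

## Model

Per lung, mass flow through the equivalent throttle of effective area
`Ae` (subsonic branch; the choked branch freezes the ratio at
`b = (2/(k+1))^{k/(k−1)}`):

```
q = Ae · p_u · √(1/θ) · √( 2k/(k−1) · 1/R · ((p_d/p_u)^{2/k} − (p_d/p_u)^{(k+1)/k}) )
```

and, from the differentiated gas law `pV = mRθ` with compliance
`C = dV/dp`:

```
dp/dt = Rθ q V / (V² + C m Rθ),   dV/dt = C dp/dt,   dm/dt = q,
q_s = q_r + q_l.
```

The reference bench: IPAP 22 / EPAP 4 cmH2O, 20 breaths/min, Ti 1 s,
Tr 0.3 s, both lungs C = 10 mL/cmH2O and d = 3.2 mm. See
`docs/methods.md` for assumptions, defaults and numerics.

## Worked example

Make the right lung stiffer than the left (C_r = 8 vs C_l = 10
mL/cmH2O) and see how the breath redistributes:

```python
from bilung import (reference_scenario, apply_parameter,
                    tidal_volumes, flow_ratio_series, metrics_frame)

traj = apply_parameter(reference_scenario(), "C_r", 8.0).run()
print(metrics_frame(tidal_volumes(traj)).to_string(index=False))
```

```
 cycle    VT_r_mL    VT_l_mL    VT_s_mL  vt_share_r
     0 144.000234 178.969137 322.969371    0.445863
     1 144.000237 178.969381 322.969617    0.445863
     2 144.000204 178.969733 322.969937    0.445863
```

The stiffer right lung takes 144 mL per breath against the left lung's
179 mL — a 44.6% share instead of 50% — and the per-cycle figures repeat
to sub-μL precision because the system has reached a periodic steady
state (`traj.steady` is `True`). Each lung's tidal volume approaches its
quasi-static limit `C·(IPAP−EPAP)` (144 and 180 mL here) because at
these settings both lungs nearly equilibrate within each phase. The
instantaneous flow split is richer than the per-breath share:

```python
fr = flow_ratio_series(traj)
print(fr.ratio[fr.valid].min(), fr.ratio[fr.valid].max())
# -0.2358...  1.4764...
```

Around the phase switches the ratio leaves [0, 1]: for a moment the two
lung flows have opposite signs while gas redistributes between the
compartments (a pendelluft-like transient). Samples where the total
flow is below 1e−7 kg/s are masked as undefined rather than clamped.

## Command line

```sh
bilung simulate scenario.yaml --out out/      # trajectory + metrics CSVs
bilung sweep sweep.yaml --out out/            # one-parameter sweep table
bilung paper-suite --out suite/               # all 7 reference sweep families
```

Scenario YAML blocks: `ventilator` (IPAP, EPAP, BPM, Ti, Tr), `lung_r` /
`lung_l` (C, d, Cd, V0), `gas`, `sim`; all keys optional, defaulting to
the reference bench.

## Acceptance script

`scripts/acceptance.py` re-simulates three headline quantities from
scratch — the steady flow-split ratio of two identical lungs, the same
split specified through equal throttle diameters, and the right-lung
tidal-volume share when C_r = 8 vs C_l = 10 mL/cmH2O — and writes them
(as percentages) to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The model is deterministic; `--seed` is accepted for interface
uniformity only.
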