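# oecmsim

A desk-scale simulator of the **organic electrochemical cardiomyocyte
(OECM)** — a circuit of five organic electrochemical transistors (OECTs)
that reproduces the ventricular action potential (AP) in hardware-realistic
voltages (hundreds of mV) and time scales (ms–s).

The package is for device and circuit researchers in organic
bioelectronics, and for cardiac-modelling readers who want a compact,
inspectable stand-in for the physical device: it lets you replay the
device-level experiments — single APs, S1–S2 refractoriness, pacing,
bias/electrolyte/pH modulation, and synchronization to cell-derived AP
trains — without a cleanroom.

## The model in brief

A membrane capacitance `C_mem` integrates three currents at the node
`V_mem`:

```
C_mem dV_mem/dt = I_in + I_NaCa(V_S, V_mem) − I_K(V_gK, V_mem) − (V_mem − V_gK)/R_dK
C_dK  dV_gK/dt  = (V_mem − V_gK)/R_dK
c_s   dV_S/dt   = inverter output-stage net current
ds_x /dt        = (gate_x − s_x)/τ_x(direction, electrolyte)
```

* the **Na/Ca charging channel** is a series p/n OECT pair from
  `E_NC = 0.6 V` to the membrane node, gated by a sensing inverter that
  thresholds `V_mem` near 0.3 V; its antiambipolar current peaks at
  ~17.2 µA when the gate crosses `(V_mem + E_NC)/2 ≈ 0.45 V`;
* the **K discharging channel** is an n-OECT to `E_K ≈ −0.1 V`, gated by
  `V_mem` through an `R_dK C_dK = 47 ms` delay and a 16.2 ms ion-doping
  lag, with a 0.29 V threshold set by its dilute 5 mM KCl electrolyte;
* OECTs follow an accumulation-mode square law with softplus subthreshold,
  finite output conductance, and electrolyte-dependent transconductance,
  threshold (Nernst-like) and switching speed; acidic pH inhibits the BBL
  n-channels (Hill law).

The interplay of a fast charging transient (phase 0), a delayed K
activation (phase 1), a metastable current balance (phase 2 plateau) and
its collapse (phase 3) produces ventricular-shaped APs, refractoriness and
all the modulation behaviours.  A Beeler–Reuter (1977) reference model is
included for side-by-side phase comparison, and a seeded synthetic beat
train plus J-inverter stage emulates cardiomyocyte-to-OECM coupling.
See `docs/methods.md` for the full account, including the calibration and
its documented limits.

## Worked example

```python
from oecmsim.presets import paper2026
from oecmsim.protocols import run_single_ap

trace, f = run_single_ap(paper2026())   # 10 µA / 20 ms pulse, E_K = −0.10 V
print(f"cls={f.cls} peak={f.v_peak:.3f} plateau={f.plateau_duration*1e3:.1f} "
      f"apd50={f.apd*1e3:.1f} rest={f.v_rest:.4f}")
```

prints

```
cls=full peak=0.341 plateau=200.5 apd50=229.6 rest=0.0124
```

i.e. the standard stimulus elicits a full AP: an upstroke to 0.341 V, a
phase-2 plateau lasting 200.5 ms, an APD50 of 229.6 ms, from a resting
potential of 12 mV.  `trace` carries the sampled node voltages and channel
currents (`t, v_mem, v_s, v_gk, i_naca, i_k, i_in` at 0.5 ms).

The same experiments are available from the shell:

```bash
oecm characterize --out out/        # steady-state VTC/CTC curves
# S-inverter switches at 0.300 V; CTC peak 17.2 uA

oecm s1s2 --config cfg.yaml --out out/   # refractoriness scan
oecm sweep --which kcl --out out/        # hyper-/hypokalemia emulation
oecm biohybrid --seed 7 --out out/       # cell-train synchronization
```

Every run writes CSV traces/tables plus a JSON summary with a provenance
block (config hash, preset version, seed).  Configurations are YAML
overlays on the `paper2026` preset (see `oecmsim.io.RunConfig`).

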