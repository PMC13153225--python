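# Methods

## The model

`oecmsim` simulates an organic electrochemical cardiomyocyte (OECM): a
five-transistor OECT circuit that emulates the ventricular action potential
(AP).  The equivalent circuit has four dynamical blocks around a membrane
node `V_mem` with capacitance `C_mem = 1 µF`:

* **Sensing inverter (S-inverter).** A matched p/n OECT pair between
  `E_S = 0.6 V` and ground, input `V_mem`, output `V_S` on a load
  capacitance `c_s`.  It thresholds the membrane voltage: its maximum-gain
  point sits at `E_S/2 = 0.3 V` for matched devices.
* **Na/Ca charging channel.** A series p/n OECT pair between
  `E_NC = 0.6 V` and the membrane node, both gates driven by `V_S`.  The
  series connection conducts only when both devices are on, producing an
  antiambipolar current that peaks when the gate sits near the midpoint of
  its effective rail, `(V_mem + E_NC)/2 ≈ 0.45 V`.  The inner node is
  solved algebraically (Brent root of the current balance, ≤1 µV) at every
  evaluation rather than being given a parasitic capacitance, which avoids
  an artificially stiff state.
* **K discharging channel.** An n-OECT from the membrane node to a small
  negative source bias `E_K ∈ [-0.15, -0.05] V`, gated by the membrane
  voltage low-pass filtered through `R_dK = 470 kΩ` into
  `C_dK = 0.1 µF` (`R_dK·C_dK = 47 ms`; `C_dK` referenced to ground) and
  additionally lagged by the slow ion-doping of its dilute 5 mM KCl
  electrolyte (`τ_on = 16.2 ms`).  Its threshold at 5 mM is 0.29 V.
* **Gate network current.** The RC branch draws `(V_mem - V_gk)/R_dK` from
  the membrane node; OECT gates are otherwise capacitively decoupled.

State vector: `[V_mem, V_gk, V_S, s_K, s_NCp, s_NCn]`, where the `s_*` are
first-order doping states (effective gate drives).  Integration uses
`scipy.solve_ivp` BDF, rtol 1e-6 / atol 1e-9, with the time axis split at
stimulus discontinuities and a 0.1 ms step cap during pulses.  Traces are
sampled at 0.5 ms.  The resting state is found by stimulus-free relaxation
(5 s blocks, up to 30 s) followed by a Newton polish of the algebraic
fixed point.

### Compact OECT model

Accumulation-mode square law with a softplus subthreshold transition of
width 10 mV, an ohmic off-conductance `g_off`, and a channel-length
modulation term `(1 + λ·|v_ds|)` that gives each device a finite output
conductance.  The λ term is essential: without it a matched inverter has
near-infinite gain and the antiambipolar conduction window collapses to
less than a millivolt, which makes a sustained plateau impossible.  The
current is antisymmetric in `v_ds` and C1-continuous across the
triode/saturation boundary.

Electrolyte laws (all normalized at the physiological reference, 5 mM KCl
for the K channel and 140 mM NaCl elsewhere):

* conductance factor `(c/c_ref)^γ` with γ = 0.35;
* threshold shift `V_th = V_th,ref − κ·ln(c/140 mM)` with κ = 5 mV
  (the K device's concentrated-reference threshold of 0.2733 V places the
  5 mM value at the measured 0.29 V);
* doping time constant `τ(c) = τ_ref·(c_ref/c)`;
* Hill-type protonation inhibition `∝ 1/(1 + ([H⁺]/K_a)^h)` of the
  ladder-polymer (BBL) n-channels, normalized to 1 at pH 7, with
  pK_a = 6.3 and h = 2.

γ, κ, pK_a and h were calibrated jointly so that the potassium and pH
modulation experiments reproduce the measured classification pattern
(see below); the remaining device constants are listed in
`presets.py` and re-derivable with `scripts/calibrate_preset.py`.

### Doping kinetics

Each OECT's effective gate drive relaxes exponentially toward its applied
gate voltage.  Doping (toward stronger accumulation) and dedoping carry
separate time constants, and dedoping is the slower process: the Na/Ca
devices dope in 0.17 ms but dedope in ~10 ms.  This asymmetry is what
produces the ~15 ms transient activation of the charging channel during
the upstroke — the pair keeps conducting while the inverter output races
past its conduction window — and the membrane overshoot to ~0.34 V.  The
K device's dedoping constant (20.3 ms at 5 mM) sets the decay of the
refractory wake and was calibrated against the measured ~240 ms absolute
refractory period.

## How an AP forms

At rest (`V_mem ≈ 0.01 V`) the charging and discharging paths balance at
~0.2 µA of leakage.  A 10 µA / 20 ms pulse charges the membrane at
10 V/s; near 0.15–0.2 V the inverter output starts sagging, the charging
pair engages regeneratively, and the upstroke runs to ~0.34 V (phase 0).
The inverter output then undershoots, the pair dedopes, and the membrane
decays slowly while the K gate charges through its 47 + 16 ms lags
(phase 1).  As `V_mem` re-enters the conduction window the charging
current catches the growing K current and the two track each other —
rising together from a few µA to ~17.5 µA — in a metastable balance near
0.27–0.29 V (phase 2, ~200 ms at `E_K = -0.10 V`).  The plateau ends when
the fully-doped K channel's capability exceeds the peak of the charging
channel's transfer curve (17.2 µA); the membrane then collapses, briefly
hyperpolarizes, and relaxes back to rest (phases 3–4).

## Feature extraction

Rest is the pre-stimulus median; the plateau is the longest slow
(|dV/dt| < 1.5 V/s) elevated stretch after the peak, its duration measured
as the contiguous dwell within ±0.03 V of the plateau level; the notch is
an interior minimum at least 5 mV below the peak when one exists; APD is
APD50 by default (APD90 selectable); dV/dt uses centered differences at
the 0.5 ms sampling.  A response is *regenerative* when the voltage keeps
rising after the stimulus ends or the upstroke exceeds 1.5× the passive
slope `I_in/C_mem`.  Classification against a reference AP: `none`
(<5 % of the reference amplitude), `subthreshold` (not regenerative),
`sustained_depolarization` (still above the plateau band 2 s after the
stimulus), `full` (≥90 % amplitude and ≥50 % plateau), else `premature`.
Swing amplitude is peak minus rest (peak minus hyperpolarization
selectable).

## Protocols

* **S1–S2 refractoriness** (onset-to-onset intervals, 5 ms grid refined to
  1 ms; the S1 leg is integrated once and each S2 branch resumes from the
  stored state).  ARP = longest interval eliciting no AP; recovery =
  shortest interval eliciting a full AP.
* **Pacing** at fixed cycle length or DC drive.
* **Bias sweeps** over `E_K` and `E_NC` with per-point APD/amplitude/class.
* **Electrolyte and pH sweeps** on the K channel, classified against the
  physiological baseline at the same bias.
* **E_K standardization**: bracketed bisection for a target APD on the
  monotone full-AP branch.

## The Beeler–Reuter reference

`br.py` implements the 1977 four-current ventricular model (I_Na, I_s,
I_K1, I_x1; gates m, h, j, d, f, x1; calcium pool) with the original
constants, in mV/ms/µA·cm⁻² units, reusing the same trace container and
feature extractor (with a mV-scaled config).  The default stimulus is
30 µA/cm² for 2 ms.  `compare_phases` tabulates per-phase durations and
normalized amplitudes of an OECM AP against a BR AP.

## The biohybrid chain

Cell electrophysiology is *not* modelled mechanistically.  A seeded
generator renders a fixed AP template (10 ms linear upstroke, exponential
repolarization, 300 ms duration) at log-normal beat intervals
(mean cycle length 1 s, CV 0.15 by default) and a small coupled amplitude
(40 mV before the κ = 0.75 coupling attenuation — the paper does not
quantify the damping fraction, so κ and the biohybrid OECT's drive
strength are free calibration parameters chosen so the J-inverter's output
pulses land in the regime that actually gates the OECM).  The J-inverter
(BBL OECT biased at `V_in = 0.3 V` with `E_J = 0.6 V`, `R_J = 180 kΩ`)
translates upward cell APs into downward output pulses via a resistive
load line solved per sample with the device's doping lag; its output
directly substitutes for `V_S` in a reduced OECM (sensing inverter out of
the loop).  The pipeline is bit-reproducible under a fixed seed.  What
the generator does not emulate: true hiPSC-CM waveform diversity,
beat-to-beat amplitude variability, field-potential shape, or
cell-device cleft impedance.

## Calibration and its limits

The preset is calibrated at the device level and judged on emergent
circuit behaviour.  Within the printed component values several
circuit-level observables cannot all be placed simultaneously; the
following trade-offs are inherent to this equivalent circuit and are left
as honest deviations rather than being tuned away:

* **Relative refractory period.**  After the plateau collapses, the K
  channel clamps the membrane near `E_K` while its gate discharges
  (47 + 20 ms).  A standard 10 µA/20 ms probe delivers only 0.2 V of
  charge, so during the clamp a second stimulus cannot re-trigger at all,
  and once the clamp releases the response is almost immediately full:
  graded premature responses are confined to a few milliseconds.  The
  simulator therefore shows ARP ≈ 240 ms but recovery ≈ 243 ms
  (RRP ≈ 2 ms) instead of the measured 320/80 ms.
* **Long-APD tail.**  Near the sustained-depolarization boundary the
  plateau duration grows only logarithmically with the ~63 ms gate time
  constant, so APDs between ~260 and 500 ms occupy a bias window of order
  10 µV — unreachable on any realistic sweep grid.  The attainable APD50
  range is ~110–255 ms (hence the E_K standardization target defaults to
  220 ms rather than the nominal 300 ms).
* **Plateau-onset balance.**  The balance current at the start of phase 2
  is fixed by the K-gate RC history over the upstroke (all constituent
  constants printed); it comes out near 9 µA rather than 5 µA.
* **E_NC slope.**  Raising the charging rail raises the plateau *level*,
  which strengthens the K drive faster than it adds charging capacity, so
  in this calibration the APD falls (monotonically) with `E_NC`.
* At biases past the sweep extremes the circuit loses its resting fixed
  point and self-paces; sweeps record such points as `autorhythmic`.

Problem sizes used throughout (single APs of 1.6–2.1 s, S1–S2 scans of
~70 branch integrations, sweeps of 40–60 points) keep any single
experiment under a couple of minutes on one CPU.

## Degenerate inputs and numerical edges

Zero electrolyte concentration, non-finite states, overlapping pulses,
non-uniform traces and malformed files raise `ValueError` with context;
solver failures raise `RuntimeError` with the failing segment.  The
series-pair root is bracketed in `[V_mem, E_NC]` where the balance is
strictly monotone; when both devices are off the solver returns the
leakage-level solution.  Rate-function singularities in the reference
model are handled by their analytic limits.
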