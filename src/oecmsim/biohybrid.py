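"""Biohybrid synchronization: cell-derived AP trains driving the OECM.

The signaling chain mirrors gap-junction conduction between ventricular
cardiomyocytes: a monolayer of stem-cell-derived cardiomyocytes sits on
the channel of a biohybrid OECT; their extracellular APs superimpose on
the OECT's gate bias (attenuated by the coupling fraction kappa); the
OECT plus a load resistor forms the junctional inverter (J-inverter) that
translates upward cell APs into downward output pulses; and that output
directly gates the OECM's Na/Ca charging channel, replacing the sensing
inverter.

Cell electrophysiology is not modelled mechanistically: a seeded
stochastic beat-train generator renders a fixed AP waveform template at
log-normally distributed beat intervals, emulating the variability of
cultured cardiomyocyte monolayers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .circuit import OECMParams, SolverOptions, Trace, simulate
from .features import APConfig, extract
from .oect import OECTParams, Polarity, SUBTHRESHOLD_WIDTH
from .stimulus import StimulusProtocol

__all__ = [
    "BeatTrainSpec",
    "JInverterParams",
    "default_biohybrid_oect",
    "generate_beat_train",
    "jinverter_vtc",
    "jinverter_response",
    "back_calculate_vin_eff",
    "drive_oecm",
    "SyncReport",
]


@dataclass(frozen=True)
class BeatTrainSpec:
    """Synthetic stochastic cardiomyocyte AP train.

    Beat intervals are log-normal with the given mean cycle length and
    coefficient of variation; each beat renders the same AP template
    (linear upstroke, exponential repolarization) at the small
    extracellular-coupled amplitude scale.  The seed fixes the realization
    exactly.
    """

    mean_cycle_length: float = 1.0   # s
    interval_cv: float = 0.15        # dimensionless
    ap_amplitude: float = 0.040      # V at the coupled (attenuated) scale
    ap_duration: float = 0.30        # s
    upstroke_time: float = 0.01      # s
    duration: float = 10.0           # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_cycle_length > self.ap_duration:
            raise ValueError("mean cycle length must exceed the AP duration")
        if self.interval_cv < 0:
            raise ValueError("interval_cv must be >= 0")


def generate_beat_train(
    spec: BeatTrainSpec, sample_dt: float = 0.5e-3
) -> Tuple[Trace, np.ndarray]:
    """Render the beat train; returns (trace, beat_onset_times).

    The trace's ``v_mem`` column holds the cell AP waveform (V); all other
    channels are zero.  Beats whose template would extend past the end of
    the record are dropped; an empty train is returned (with a warning in
    the metadata) if the duration admits no beat.
    """
    rng = np.random.default_rng(spec.seed)
    t_beats = []
    t = 0.1 * spec.mean_cycle_length  # short lead-in before the first beat
    while t + spec.ap_duration < spec.duration:
        t_beats.append(t)
        if spec.interval_cv == 0:
            dt_beat = spec.mean_cycle_length
        else:
            sigma2 = math.log(1.0 + spec.interval_cv**2)
            mu = math.log(spec.mean_cycle_length) - 0.5 * sigma2
            dt_beat = float(rng.lognormal(mu, math.sqrt(sigma2)))
        dt_beat = max(dt_beat, 1.1 * spec.ap_duration)  # no overlapping beats
        t += dt_beat
    n = int(round(spec.duration / sample_dt)) + 1
    tt = np.arange(n) * sample_dt
    v = np.zeros(n)
    tau_rep = spec.ap_duration / 3.0
    for tb in t_beats:
        rel = tt - tb
        m_up = (rel >= 0) & (rel < spec.upstroke_time)
        v[m_up] += spec.ap_amplitude * rel[m_up] / spec.upstroke_time
        m_rep = (rel >= spec.upstroke_time) & (rel < spec.ap_duration + 0.2)
        x = rel[m_rep] - spec.upstroke_time
        v[m_rep] += spec.ap_amplitude * np.exp(-x / tau_rep)
    meta = {"beats": list(map(float, t_beats)), "seed": spec.seed}
    if not t_beats:
        meta["warning"] = "duration too short for a single beat"
    z = np.zeros(n)
    trace = Trace(t=tt, v_mem=v, v_s=z, v_gk=z.copy(), i_naca=z.copy(),
                  i_k=z.copy(), i_in=z.copy(), meta=meta)
    return trace, np.array(t_beats)


def default_biohybrid_oect() -> OECTParams:
    """Compact model of the BBL biohybrid OECT (cell-culture electrolyte)."""
    return OECTParams(
        name="biohybrid",
        polarity=Polarity.n,
        beta=2.5e-3,
        v_th_ref=0.31,
        g_off=0.05e-6,
        tau_on_ref=0.5e-3,
        tau_off_ref=2.0e-3,
        lam=0.5,
        ph_sensitive=True,
        geometry={"W_um": 10, "L_um": 10},
    )


@dataclass(frozen=True)
class JInverterParams:
    """Junctional inverter: biohybrid OECT plus load resistor."""

    v_in: float = 0.3                # V, gate operating bias
    e_j: float = 0.6                 # V, supply
    r_j: float = 180e3               # Ohm, load resistance
    biohybrid_oect: OECTParams = field(default_factory=default_biohybrid_oect)
    kappa: float = 0.75              # coupling attenuation of the cell AP

    def __post_init__(self) -> None:
        if not self.r_j > 0:
            raise ValueError("r_j must be > 0")
        if not (0.0 < self.kappa <= 1.0):
            raise ValueError("kappa must lie in (0, 1]")


def _dev_i(o: OECTParams, v_gs: float, v_ds: float) -> float:
    sigma = 1.0 if o.polarity is Polarity.n else -1.0
    ur = sigma * (v_gs - o.v_th_ref)
    x = ur / SUBTHRESHOLD_WIDTH
    if x > 40.0:
        u = ur
    elif x < -40.0:
        u = 0.0
    else:
        u = SUBTHRESHOLD_WIDTH * math.log1p(math.exp(x))
    xds = sigma * v_ds
    ax = abs(xds)
    if ax < u:
        imag = o.beta * (u - 0.5 * ax) * ax * (1.0 + o.lam * ax)
    else:
        imag = 0.5 * o.beta * u * u * (1.0 + o.lam * ax)
    return sigma * math.copysign(imag, xds) + o.g_off * v_ds


def _load_line(params: JInverterParams, v_gate: float) -> float:
    """Quasi-static J-inverter output for a given effective gate voltage."""
    o = params.biohybrid_oect

    def f(v_out: float) -> float:
        return params.e_j - v_out - _dev_i(o, v_gate, v_out) * params.r_j

    lo, hi = 0.0, params.e_j
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return lo if abs(flo) < abs(fhi) else hi
    return brentq(f, lo, hi, xtol=1e-9, rtol=8.9e-16)


def jinverter_vtc(params: JInverterParams, v_in_grid: np.ndarray) -> dict:
    """Steady-state voltage transfer curve v_in_eff -> v_out."""
    grid = np.asarray(v_in_grid, dtype=float)
    v_out = np.array([_load_line(params, v) for v in grid])
    return {"v_in": grid, "v_out": v_out}


def jinverter_response(
    params: JInverterParams, v_ap_trace: Trace
) -> Trace:
    """Translate a cell AP train into the J-inverter's output waveform.

    The effective gate voltage is v_in + kappa * v_ap(t); the OECT's doping
    lag filters it (doping fast, dedoping slower), and the output follows
    the resistive load line, so upward cell APs appear as downward v_out
    pulses.
    """
    t = v_ap_trace.t
    v_ap = v_ap_trace.v_mem
    dt = v_ap_trace.dt
    o = params.biohybrid_oect
    v_out = np.empty_like(v_ap)
    s = params.v_in + params.kappa * v_ap[0]
    for k in range(len(t)):
        target = params.v_in + params.kappa * v_ap[k]
        tau = o.tau_on_ref if target > s else o.tau_off_ref
        s = target + (s - target) * math.exp(-dt / tau)
        v_out[k] = _load_line(params, s)
    z = np.zeros_like(v_out)
    return Trace(
        t=t.copy(), v_mem=v_ap.copy(), v_s=v_out, v_gk=z, i_naca=z.copy(),
        i_k=z.copy(), i_in=z.copy(),
        meta={**v_ap_trace.meta, "v_out_column": "v_s"},
    )


def back_calculate_vin_eff(
    params: JInverterParams,
    v_out: np.ndarray,
    vtc: Optional[dict] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Invert the VTC pointwise: v_out samples -> effective input voltage.

    Returns (v_in_eff, out_of_range_mask); samples outside the VTC's output
    range are flagged, not silently clipped.
    """
    if vtc is None:
        vtc = jinverter_vtc(params, np.arange(0.0, 0.6001, 0.0005))
    v_in_grid = np.asarray(vtc["v_in"])
    v_out_grid = np.asarray(vtc["v_out"])
    order = np.argsort(v_out_grid)
    vo_sorted = v_out_grid[order]
    vi_sorted = v_in_grid[order]
    if not np.all(np.diff(vo_sorted) >= -1e-12):
        raise ValueError("VTC is not monotone over the operating range")
    v_out = np.asarray(v_out, dtype=float)
    flagged = (v_out < vo_sorted[0] - 1e-9) | (v_out > vo_sorted[-1] + 1e-9)
    v_in_eff = np.interp(v_out, vo_sorted, vi_sorted)
    return v_in_eff, flagged


@dataclass
class SyncReport:
    """Counts and latencies of vCM-to-OECM synchronization."""

    n_input_pulses: int
    n_aps: int
    latencies_s: list
    skipped: int

    def as_dict(self) -> dict:
        return {
            "n_input_pulses": self.n_input_pulses,
            "n_aps": self.n_aps,
            "latencies_ms": [round(x * 1e3, 3) for x in self.latencies_s],
            "skipped": self.skipped,
        }


def drive_oecm(
    v_out_trace: Trace,
    params: OECMParams,
    beat_times: Optional[np.ndarray] = None,
    options: SolverOptions = SolverOptions(),
    ap_threshold_frac: float = 0.5,
) -> Tuple[Trace, SyncReport]:
    """Drive the OECM's Na/Ca gate directly with a recorded J-inverter output.

    The sensing inverter is out of the loop: ``v_out`` substitutes for V_S.
    Input pulses are the downward v_out deflections (or the provided beat
    times); an elicited OECM AP is an upstroke exceeding the given fraction
    of the standard AP amplitude.  Pulses arriving inside the refractory
    wake of the previous AP elicit nothing and are counted as skipped.
    """
    v_out = v_out_trace.v_s if np.any(v_out_trace.v_s) else v_out_trace.v_mem
    t = v_out_trace.t
    proto = StimulusProtocol(mode="external_gate", external=(t, v_out))
    duration = float(t[-1] - t[0])
    trace = simulate(params, proto, duration, options)

    if beat_times is None:
        beat_times = _downward_pulse_onsets(t, v_out)
    beat_times = np.asarray(beat_times, dtype=float)

    rest = trace.v_mem[0]
    v_span = float(np.max(trace.v_mem) - rest)
    thr = rest + ap_threshold_frac * max(v_span, 0.1)
    release = rest + 0.25 * max(v_span, 0.1)
    # hysteretic upstroke detector: one count per excursion above thr,
    # re-armed only after the voltage falls back below the release level
    ap_times = []
    armed = True
    for k, v in enumerate(trace.v_mem):
        if armed and v > thr:
            ap_times.append(trace.t[k])
            armed = False
        elif not armed and v < release:
            armed = True
    ap_times = np.asarray(ap_times)

    latencies = []
    used = np.zeros(len(ap_times), dtype=bool)
    for tb in beat_times:
        k = np.searchsorted(ap_times, tb)
        if k < len(ap_times) and not used[k] and ap_times[k] - tb < 0.3:
            used[k] = True
            latencies.append(float(ap_times[k] - tb))
    report = SyncReport(
        n_input_pulses=int(len(beat_times)),
        n_aps=int(len(ap_times)),
        latencies_s=latencies,
        skipped=int(len(beat_times) - len(latencies)),
    )
    return trace, report


def _downward_pulse_onsets(t: np.ndarray, v_out: np.ndarray) -> np.ndarray:
    base = float(np.median(v_out))
    depth = base - np.min(v_out)
    if depth <= 0:
        return np.array([])
    thr = base - 0.5 * depth
    below = v_out < thr
    onsets = np.flatnonzero(~below[:-1] & below[1:]) + 1
    return t[onsets]
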