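"""Stimulation experiments on the OECM circuit.

Single-pulse APs, S1-S2 refractoriness scans, paced trains, DC drive,
bias sweeps (E_NC, E_K), electrolyte ([KCl]) and pH sweeps, and the E_K
standardization procedure that benchmarks a device to a target APD.

Conventions: the standard stimulus is a 10 uA, 20 ms square pulse; S1-S2
intervals are measured stimulus onset to stimulus onset; APD is APD50 by
default (configurable).  All sweeps are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit import OECMParams, SolverOptions, Trace, simulate
from .features import (
    APConfig,
    APFeatures,
    ClassifyThresholds,
    classify_response,
    extract,
)
from .oect import ElectrolyteCondition
from .stimulus import Pulse, StimulusProtocol

__all__ = [
    "STANDARD_PULSE_AMP",
    "STANDARD_PULSE_WIDTH",
    "RefractorinessResult",
    "standard_pulse",
    "ap_config_for",
    "run_single_ap",
    "s1s2_scan",
    "paced_train",
    "bias_sweep",
    "electrolyte_sweep",
    "ph_sweep",
    "calibrate_ek",
]

STANDARD_PULSE_AMP = 10e-6    # A
STANDARD_PULSE_WIDTH = 20e-3  # s
STANDARD_ONSET = 0.05         # s of pre-stimulus baseline


def standard_pulse(
    t0: float = STANDARD_ONSET,
    amplitude: float = STANDARD_PULSE_AMP,
    width: float = STANDARD_PULSE_WIDTH,
) -> Pulse:
    return Pulse(t0, amplitude, width)


def ap_config_for(params: OECMParams, pulse: Pulse, **overrides) -> APConfig:
    """Feature-extraction config matched to a stimulus and circuit."""
    defaults = dict(
        stim_onset=pulse.t0,
        stim_end=pulse.t0 + pulse.width,
        passive_slope=abs(pulse.amplitude) / params.c_mem,
    )
    defaults.update(overrides)
    return APConfig(**defaults)


def run_single_ap(
    params: OECMParams,
    pulse: Optional[Pulse] = None,
    duration: Optional[float] = None,
    options: SolverOptions = SolverOptions(),
    ap_config: Optional[APConfig] = None,
) -> Tuple[Trace, APFeatures]:
    """Simulate one stimulus episode and extract its AP features."""
    if pulse is None:
        pulse = standard_pulse()
    if duration is None:
        duration = pulse.t0 + pulse.width + 2.05  # sustained check needs 2 s
    proto = StimulusProtocol(pulses=(pulse,))
    trace = simulate(params, proto, duration, options)
    cfg = ap_config if ap_config is not None else ap_config_for(params, pulse)
    feats = extract(trace, cfg)
    return trace, feats


@dataclass
class RefractorinessResult:
    """Outcome of an S1-S2 scan (all intervals onset-to-onset, seconds)."""

    arp: float
    rrp: float
    recovery_interval: float
    records: pd.DataFrame  # interval_s, cls, amplitude_V, plateau_s

    def __post_init__(self) -> None:
        if not math.isclose(self.recovery_interval, self.arp + self.rrp,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("recovery_interval must equal arp + rrp")


_NO_AP = ("none", "subthreshold")


def s1s2_scan(
    params: OECMParams,
    intervals: Optional[Sequence[float]] = None,
    pulse: Optional[Pulse] = None,
    refine_step: float = 1e-3,
    options: SolverOptions = SolverOptions(),
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    response_window: float = 0.9,
) -> RefractorinessResult:
    """Two-pulse refractoriness scan.

    S1 fires from rest; S2 follows after each tested interval.  The S2
    response is classified against the S1 reference (none/subthreshold =
    no AP initiated, premature, full).  ARP is the longest interval that
    elicits no AP; the recovery interval is the shortest that elicits a
    full AP; RRP is their difference.  Boundaries found on the coarse grid
    are refined by a local scan at ``refine_step`` (1 ms default).

    The S1 leg is integrated once; each S2 branch resumes from the stored
    S1 state 20 ms before the S2 onset.
    """
    if pulse is None:
        pulse = standard_pulse()
    if intervals is None:
        intervals = np.arange(0.100, 0.4001, 0.005)
    intervals = np.asarray(sorted(intervals), dtype=float)
    if intervals.size < 2:
        raise ValueError("interval grid too small")

    # S1 reference AP
    ref_trace, ref = run_single_ap(params, pulse, options=options)
    if ref.cls != "full":
        raise RuntimeError(f"S1 did not produce a full AP (got {ref.cls})")

    # one long S1 run whose states seed every S2 branch
    t_max = pulse.t0 + intervals[-1] + response_window
    base = simulate(
        params, StimulusProtocol(pulses=(pulse,)), t_max, options, keep_states=True
    )
    states = base.meta["states"]
    dt = base.dt

    lead = 0.02  # s of pre-S2 baseline carried into the response segment

    def classify_at(interval: float) -> Tuple[str, APFeatures]:
        t2 = pulse.t0 + interval
        j = int(round((t2 - lead) / dt))
        y0 = states[:, j]
        local_pulse = Pulse(lead, pulse.amplitude, pulse.width)
        proto = StimulusProtocol(pulses=(local_pulse,))
        tr = simulate(
            params,
            proto,
            lead + response_window,
            options,
            y0=y0,
            t_offset=t2 - lead,
        )
        tr = Trace(
            t=tr.t - tr.t[0], v_mem=tr.v_mem, v_s=tr.v_s, v_gk=tr.v_gk,
            i_naca=tr.i_naca, i_k=tr.i_k, i_in=tr.i_in, meta=tr.meta,
        )
        cfg = APConfig(
            stim_onset=lead,
            stim_end=lead + pulse.width,
            passive_slope=abs(pulse.amplitude) / params.c_mem,
            plateau_level_hint=ref.plateau_level,
            analysis_window=response_window - pulse.width - lead,
        )
        f = extract(tr, cfg)
        return classify_response(f, ref, thresholds), f

    rows = []
    for iv in intervals:
        cls, f = classify_at(iv)
        rows.append((iv, cls, f.amplitude, f.plateau_duration))

    classes = [r[1] for r in rows]
    if classes[0] not in _NO_AP:
        raise RuntimeError("interval grid too narrow: S2 already excitable at "
                           f"{intervals[0]*1e3:.0f} ms")
    if "full" not in classes:
        raise RuntimeError("interval grid too narrow: no full recovery up to "
                           f"{intervals[-1]*1e3:.0f} ms")

    arp_coarse = max(iv for iv, c in zip(intervals, classes) if c in _NO_AP)
    rec_coarse = min(iv for iv, c in zip(intervals, classes) if c == "full")

    # refine ARP: step forward from the last no-AP interval
    arp = arp_coarse
    iv = arp_coarse + refine_step
    while iv < rec_coarse - 1e-9:
        cls, f = classify_at(iv)
        rows.append((iv, cls, f.amplitude, f.plateau_duration))
        if cls in _NO_AP:
            arp = iv
            iv += refine_step
        else:
            break
    # refine recovery: step backward from the first full interval
    rec = rec_coarse
    iv = rec_coarse - refine_step
    while iv > arp + 1e-9:
        cls, f = classify_at(iv)
        rows.append((iv, cls, f.amplitude, f.plateau_duration))
        if cls == "full":
            rec = iv
            iv -= refine_step
        else:
            break

    records = pd.DataFrame(
        sorted(rows), columns=["interval_s", "cls", "amplitude_V", "plateau_s"]
    )
    return RefractorinessResult(
        arp=float(arp),
        rrp=float(rec - arp),
        recovery_interval=float(rec),
        records=records,
    )


def paced_train(
    params: OECMParams,
    cycle_length: float,
    n_beats: int,
    pulse_amplitude: float = STANDARD_PULSE_AMP,
    pulse_width: float = STANDARD_PULSE_WIDTH,
    dc: bool = False,
    options: SolverOptions = SolverOptions(),
) -> Tuple[Trace, List[APFeatures]]:
    """Periodic pacing (or DC drive) with per-beat feature extraction."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if dc:
        proto = StimulusProtocol(mode="dc", dc_amplitude=pulse_amplitude)
        duration = cycle_length * n_beats + STANDARD_ONSET
        trace = simulate(params, proto, duration, options)
        return trace, []
    pulses = tuple(
        Pulse(STANDARD_ONSET + k * cycle_length, pulse_amplitude, pulse_width)
        for k in range(n_beats)
    )
    proto = StimulusProtocol(pulses=pulses)
    duration = STANDARD_ONSET + cycle_length * n_beats + 0.6
    trace = simulate(params, proto, duration, options)

    feats = []
    for k, p in enumerate(pulses):
        t_end = p.t0 + cycle_length if k < n_beats - 1 else trace.t[-1]
        seg = trace.window(max(p.t0 - 0.02, 0.0), min(t_end, trace.t[-1]))
        seg = Trace(
            t=seg.t - seg.t[0], v_mem=seg.v_mem, v_s=seg.v_s, v_gk=seg.v_gk,
            i_naca=seg.i_naca, i_k=seg.i_k, i_in=seg.i_in, meta=seg.meta,
        )
        cfg = APConfig(
            stim_onset=min(0.02, p.t0),
            stim_end=min(0.02, p.t0) + p.width,
            passive_slope=abs(p.amplitude) / params.c_mem,
            analysis_window=max(t_end - p.t0 - p.width - 0.05, 0.1),
        )
        feats.append(extract(seg, cfg))
    return trace, feats


def _ap_row(
    params: OECMParams,
    options: SolverOptions,
    reference: Optional[APFeatures] = None,
) -> dict:
    try:
        _, f = run_single_ap(params, options=options)
    except RuntimeError:
        # no stable resting point at this bias: the circuit self-paces
        return {"apd_s": None, "amplitude_V": None, "plateau_s": None,
                "cls": "autorhythmic"}
    cls = f.cls if reference is None else classify_response(f, reference)
    return {
        "apd_s": f.apd if cls == "full" else None,
        "amplitude_V": f.amplitude,
        "plateau_s": f.plateau_duration,
        "cls": cls,
    }


def bias_sweep(
    params: OECMParams,
    which: str,
    grid: Iterable[float],
    options: SolverOptions = SolverOptions(),
) -> pd.DataFrame:
    """APD and swing amplitude of one standard AP per bias value.

    ``which`` selects the swept supply: 'E_NC' (charging rail) or 'E_K'
    (discharging source bias).  Failed depolarization or repolarization is
    recorded as its response class, never raised.
    """
    if which not in ("E_NC", "E_K"):
        raise ValueError("which must be 'E_NC' or 'E_K'")
    rows = []
    for b in grid:
        p = params.with_updates(e_nc=b) if which == "E_NC" else params.with_updates(e_k=b)
        row = {"bias_V": float(b), **_ap_row(p, options)}
        rows.append(row)
    return pd.DataFrame(rows)


def _with_kcl(params: OECMParams, kcl_mM: float, ph: Optional[float] = None) -> OECMParams:
    elec = dict(params.electrolytes)
    old = elec["K_channel"]
    elec["K_channel"] = ElectrolyteCondition(
        nacl_mM=old.nacl_mM, kcl_mM=kcl_mM, ph=old.ph if ph is None else ph
    )
    return params.with_updates(electrolytes=elec)


def electrolyte_sweep(
    params: OECMParams,
    kcl_grid: Iterable[float],
    options: SolverOptions = SolverOptions(),
) -> pd.DataFrame:
    """AP response versus [KCl] in the K-channel gating electrolyte.

    Emulates hyper-/hypokalemia: dilute KCl weakens and slows the
    discharging channel (longer APD, ultimately sustained depolarization);
    concentrated KCl strengthens it (shorter APD, ultimately a premature
    spike without plateau).
    """
    _, ref = run_single_ap(params, options=options)  # physiological baseline
    rows = []
    for c in kcl_grid:
        p = _with_kcl(params, float(c))
        rows.append({"kcl_mM": float(c), **_ap_row(p, options, reference=ref)})
    return pd.DataFrame(rows)


def ph_sweep(
    params: OECMParams,
    ph_grid: Iterable[float],
    options: SolverOptions = SolverOptions(),
) -> pd.DataFrame:
    """AP response versus pH of the K-channel gating electrolyte.

    Acidification protonates the BBL channel and inhibits its conductance
    (emulating acidosis): mild acidity prolongs the APD; strong acidity
    abolishes repolarization.
    """
    _, ref = run_single_ap(params, options=options)  # neutral-pH baseline
    rows = []
    for ph in ph_grid:
        old = params.electrolytes["K_channel"]
        p = _with_kcl(params, old.kcl_mM, ph=float(ph))
        rows.append({"ph": float(ph), **_ap_row(p, options, reference=ref)})
    return pd.DataFrame(rows)


def calibrate_ek(
    params: OECMParams,
    target_apd: float = 0.300,
    tolerance: float = 0.010,
    lo: float = -0.15,
    hi: float = -0.05,
    options: SolverOptions = SolverOptions(),
    max_iter: int = 30,
) -> float:
    """Standardize a device: bisection on E_K for a target APD (seconds).

    APD shrinks as E_K becomes more negative; non-repolarizing responses at
    the weak-discharge end are treated as unbounded APD.
    """

    def apd_at(ek: float) -> float:
        _, f = run_single_ap(params.with_updates(e_k=ek), options=options)
        if f.cls == "full" and f.apd is not None:
            return f.apd
        if f.cls in ("sustained_depolarization",):
            return math.inf
        return 0.0  # failed depolarization: effectively zero duration

    # the APD is monotone only inside the full-AP window, which may not
    # span the whole allowed E_K range: bracket on a coarse grid first
    grid = np.linspace(lo, hi, 11)
    apds = [apd_at(b) for b in grid]
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], apds[:-1], apds[1:]):
        lo_v, hi_v = min(fa, fb), max(fa, fb)
        # a valid bracket lies on the continuous full-AP branch: both
        # endpoints must be genuine finite APDs
        if (lo_v <= target_apd <= hi_v and np.isfinite(hi_v) and lo_v > 0):
            bracket = (a, b, fa, fb)
            break
    if bracket is None:
        finite = [x for x in apds if np.isfinite(x) and x > 0]
        rng = (f"[{min(finite)*1e3:.0f}, {max(finite)*1e3:.0f}] ms"
               if finite else "none")
        raise ValueError(
            f"target APD {target_apd*1e3:.0f} ms outside achievable range "
            f"{rng} for E_K in [{lo}, {hi}] V"
        )
    a, b, fa, fb = bracket
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        apd = apd_at(mid)
        if abs(apd - target_apd) <= tolerance:
            return mid
        # APD increases toward less negative E_K within the window
        if (apd > target_apd) == (fb > fa):
            b = mid
        else:
            a = mid
        if abs(b - a) < 1e-5:
            break
    return 0.5 * (a + b)
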