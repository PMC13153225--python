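"""Action-potential morphology extraction and response classification.

Works on any uniformly sampled voltage trace containing at most one
stimulated episode: the OECM circuit, the Beeler-Reuter reference model
(pass a config scaled to mV), or biohybrid output segments.

Landmarks: resting level from the pre-stimulus samples; peak and maximum
upstroke slope; the notch (phase-1 local minimum between the peak and the
plateau, when one exists); the plateau as the longest slow, elevated
stretch after the peak, with its duration measured by a fixed voltage band
around the plateau level; APD at a configurable repolarization fraction
(APD50 by default); and the phase-4 hyperpolarization minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circuit import Trace

__all__ = ["APConfig", "APFeatures", "extract", "classify_response"]

CLASSES = ("full", "premature", "subthreshold", "sustained_depolarization", "none")


@dataclass(frozen=True)
class APConfig:
    """Extraction settings (voltages in the units of the trace)."""

    stim_onset: Optional[float] = None   # s, start of the stimulus
    stim_end: Optional[float] = None     # s, end of the stimulus
    plateau_band: float = 0.03           # +/- band around the plateau level
    notch_min_depth: float = 0.005       # minimum dip below peak to call a notch
    dvdt_slow: float = 1.5               # V/s, |dv/dt| bound defining the plateau
    elevated_frac: float = 0.25          # plateau must sit this far above rest
    apd_fraction: float = 0.5            # 0.5 -> APD50, 0.1 -> APD90
    min_amplitude: float = 0.01          # below this the response is "none"
    regen_rise: float = 0.005            # post-stimulus rise marking regeneration
    analysis_window: float = 2.0         # s after stim_end for the sustained check
    amplitude_mode: str = "peak_minus_rest"  # or "peak_minus_hyperpolarization"
    passive_slope: Optional[float] = None  # V/s, stimulus-only dv/dt = I_in/C_mem
    plateau_level_hint: Optional[float] = None  # fix the plateau level (e.g. from a
                                                # reference AP) instead of estimating it


@dataclass
class APFeatures:
    """Extracted morphology of one AP episode."""

    v_rest: float = math.nan
    v_peak: float = math.nan
    t_peak: float = math.nan
    amplitude: float = math.nan
    dvdt_max: float = math.nan           # V/s on the upstroke
    notch_min: Optional[float] = None
    t_notch: Optional[float] = None
    plateau_level: Optional[float] = None
    plateau_start: Optional[float] = None
    plateau_end: Optional[float] = None
    plateau_duration: float = 0.0
    apd: Optional[float] = None
    hyperpolarization_min: Optional[float] = None
    regenerative: bool = False
    sustained: bool = False
    phases: dict = field(default_factory=dict)   # phase id -> (t_start, t_end)
    cls: Optional[str] = None

    def as_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, float) and math.isnan(v):
                out[k] = None
            elif isinstance(v, dict):
                out[k] = {str(p): list(b) for p, b in v.items()}
            else:
                out[k] = v
        return out


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where v crosses `level` between i-1 and i."""
    if i == 0 or v[i] == v[i - 1]:
        return float(t[i])
    frac = (level - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extract(trace: Trace, config: APConfig = APConfig()) -> APFeatures:
    """Extract AP morphology from a uniformly sampled single-episode trace."""
    t = np.asarray(trace.t, dtype=float)
    v = np.asarray(trace.v_mem, dtype=float)
    if t.size < 5:
        raise ValueError("trace too short for feature extraction")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-12):
        raise ValueError("trace must be uniformly sampled")

    f = APFeatures()
    # resting level from the pre-stimulus stretch (or the first sample)
    if config.stim_onset is not None:
        pre = v[t < config.stim_onset - 1e-12]
        f.v_rest = float(np.median(pre)) if pre.size else float(v[0])
        i_start = int(np.searchsorted(t, config.stim_onset))
    else:
        f.v_rest = float(v[0])
        i_start = 0

    seg_v = v[i_start:]
    seg_t = t[i_start:]
    ipk = int(np.argmax(seg_v)) + i_start
    f.v_peak = float(v[ipk])
    f.t_peak = float(t[ipk])
    f.amplitude = f.v_peak - f.v_rest

    dvdt = np.gradient(v, dt)
    if ipk > i_start:
        f.dvdt_max = float(np.max(dvdt[i_start : ipk + 1]))
    else:
        f.dvdt_max = float(dvdt[ipk])

    # regeneration: the voltage keeps rising after the stimulus ends, or the
    # upstroke outruns the purely capacitive (passive) stimulus slope
    if config.stim_end is not None:
        ie = int(np.searchsorted(t, config.stim_end))
        if ie < len(v) - 1:
            f.regenerative = bool(np.max(v[ie:]) - v[ie] > config.regen_rise)
        if not f.regenerative and config.passive_slope is not None:
            f.regenerative = bool(f.dvdt_max > 1.5 * config.passive_slope)
    else:
        f.regenerative = f.amplitude > config.min_amplitude

    if f.amplitude < config.min_amplitude:
        f.cls = "none"
        f.phases = {}
        return f

    # plateau: longest slow elevated stretch after the peak (or, with a
    # level hint, the longest in-band dwell after the peak)
    band = config.plateau_band
    if config.plateau_level_hint is not None:
        level = config.plateau_level_hint
        inband = np.abs(v[ipk:] - level) <= band
        runs = _runs(inband)
        plateau = None
        if runs:
            r0, r1 = max(runs, key=lambda r: r[1] - r[0])
            if (r1 - r0) * dt > 0.005:
                plateau = (r0 + ipk, r1 + ipk)
    else:
        elevated = f.v_rest + config.elevated_frac * f.amplitude
        after = slice(ipk, len(v))
        slow = (np.abs(dvdt[after]) < config.dvdt_slow) & (v[after] > elevated)
        runs = _runs(slow)
        plateau = None
        if runs:
            r0, r1 = max(runs, key=lambda r: r[1] - r[0])
            if (r1 - r0) * dt > 0.01:  # at least 10 ms of slow stretch
                plateau = (r0 + ipk, r1 + ipk)
        if plateau is not None:
            level = float(np.median(v[plateau[0]:plateau[1]]))
    if plateau is not None:
        p0, p1 = plateau
        # expand to the full contiguous in-band interval
        while p0 > ipk and abs(v[p0 - 1] - level) <= band:
            p0 -= 1
        while p1 < len(v) and abs(v[p1] - level) <= band:
            p1 += 1
        f.plateau_level = float(level)
        f.plateau_start = float(t[p0])
        f.plateau_end = float(t[min(p1, len(v) - 1)])
        f.plateau_duration = f.plateau_end - f.plateau_start

        # notch: minimum between peak and plateau start; only a genuine
        # interior dip at least notch_min_depth below the peak qualifies
        if p0 > ipk + 1:
            inotch = int(np.argmin(v[ipk:p0 + 1])) + ipk
            depth_ok = f.v_peak - v[inotch] >= config.notch_min_depth
            interior = ipk < inotch < p0 or inotch == p0
            if depth_ok and interior:
                f.notch_min = float(v[inotch])
                f.t_notch = float(t[inotch])
        iend = min(p1, len(v) - 1)
    else:
        iend = ipk

    # hyperpolarization after the plateau (or after the peak if none)
    if iend < len(v) - 1:
        f.hyperpolarization_min = float(np.min(v[iend:]))

    # APD at the configured repolarization fraction
    level_apd = f.v_rest + config.apd_fraction * f.amplitude
    up = None
    for i in range(i_start + 1, ipk + 1):
        if v[i - 1] < level_apd <= v[i]:
            up = _interp_crossing(t, v, i, level_apd)
            break
    down = None
    for i in range(ipk + 1, len(v)):
        if v[i - 1] >= level_apd > v[i]:
            down = _interp_crossing(t, v, i, level_apd)
            break
    if up is not None and down is not None:
        f.apd = down - up

    # sustained depolarization: still above the plateau band's lower edge at
    # the end of the analysis window
    t_check = (
        config.stim_end + config.analysis_window
        if config.stim_end is not None
        else t[-1]
    )
    icheck = min(int(np.searchsorted(t, t_check)), len(v) - 1)
    lower_edge = (
        f.plateau_level - config.plateau_band
        if f.plateau_level is not None
        else f.v_rest + 0.5 * f.amplitude
    )
    # a sustained depolarization needs an AP-scale excursion; small passive
    # bumps that have not decayed yet are not "sustained"
    f.sustained = bool(
        v[icheck] > lower_edge and f.amplitude >= 10.0 * config.min_amplitude
    )

    if config.amplitude_mode == "peak_minus_hyperpolarization" and (
        f.hyperpolarization_min is not None
    ):
        f.amplitude = f.v_peak - f.hyperpolarization_min

    # phase boundaries
    phases = {}
    t0 = config.stim_onset if config.stim_onset is not None else float(t[i_start])
    phases[0] = (t0, f.t_peak)
    if f.plateau_start is not None:
        phases[1] = (f.t_peak, f.plateau_start)
        phases[2] = (f.plateau_start, f.plateau_end)
        # phase 3: from plateau end to return near rest
        ie = int(np.searchsorted(t, f.plateau_end))
        back = None
        if ie < len(v):
            ihyp = ie + int(np.argmin(v[ie:]))
            for i in range(ihyp, len(v)):
                if abs(v[i] - f.v_rest) <= 0.1 * f.amplitude:
                    back = float(t[i])
                    break
        if back is not None:
            phases[3] = (f.plateau_end, back)
            phases[4] = (back, float(t[-1]))
    f.phases = phases

    # standalone classification (no reference)
    if f.sustained:
        f.cls = "sustained_depolarization"
    elif not f.regenerative:
        f.cls = "subthreshold"
    elif f.plateau_duration > 0:
        f.cls = "full"
    else:
        f.cls = "premature"
    return f


def _runs(mask: np.ndarray):
    """(start, end) index pairs of contiguous True runs."""
    out = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


@dataclass(frozen=True)
class ClassifyThresholds:
    amplitude_frac: float = 0.9     # "full" requires >= this fraction of S1 amp
    plateau_frac: float = 0.5       # and >= this fraction of the S1 plateau
    none_frac: float = 0.05         # below this amplitude fraction -> none


def classify_response(
    features: APFeatures,
    reference: APFeatures,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> str:
    """Classify a response against a reference full AP.

    Deterministic rules: `none` for an essentially flat response,
    `subthreshold` for a passive (non-regenerative) bump,
    `sustained_depolarization` when the voltage has not repolarized by the
    end of the analysis window, `full` when amplitude and plateau both reach
    the reference fractions, otherwise `premature`.
    """
    if not reference.amplitude or reference.amplitude <= 0:
        raise ValueError("reference must contain a full AP")
    if features.amplitude < thresholds.none_frac * reference.amplitude:
        return "none"
    if not features.regenerative:
        return "subthreshold"
    if features.sustained:
        return "sustained_depolarization"
    if (
        features.amplitude >= thresholds.amplitude_frac * reference.amplitude
        and features.plateau_duration >= thresholds.plateau_frac * reference.plateau_duration
    ):
        return "full"
    return "premature"
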