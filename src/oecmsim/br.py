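"""Beeler-Reuter (1977) ventricular action-potential model.

The four-current, eight-state ODE description of mammalian ventricular
excitability: fast inward sodium current I_Na, slow inward (calcium)
current I_s, time-independent outward potassium current I_K1, and the
time-activated outward current I_x1, with Hodgkin-Huxley-type gates
m, h, j, d, f, x1 and an intracellular calcium pool.  Constants follow the
original 1977 formulation.  Voltages are in mV, time in ms, currents in
uA/cm^2, C_m = 1 uF/cm^2.

The simulator reuses the :class:`~oecmsim.circuit.Trace` container (with
mV-scale voltages in the ``v_mem`` column) so that the AP feature extractor
applies unchanged; pass it a config scaled to millivolts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .circuit import Trace
from .features import APConfig, APFeatures, extract
from .stimulus import StimulusProtocol, Pulse

__all__ = [
    "BRState",
    "BR_GATES",
    "rate_constants",
    "gate_steady_state",
    "br_derivatives",
    "br_simulate",
    "br_ap_config",
    "compare_phases",
]

C_M = 1.0          # uF/cm^2
G_NA = 4.0         # mS/cm^2
G_NAC = 0.003      # mS/cm^2, background sodium
E_NA = 50.0        # mV
G_S = 0.09         # mS/cm^2, slow inward conductance

BR_GATES = ("m", "h", "j", "d", "f", "x1")

# Generalized-exponential rate constants (C1..C7) of the 1977 model:
# rate = (C1*exp(C2*(V+C3)) + C4*(V+C5)) / (exp(C6*(V+C3)) + C7)
_RATE_TABLE = {
    ("m", "alpha"): (0.0, 0.0, 47.0, -1.0, 47.0, -0.1, -1.0),
    ("m", "beta"): (40.0, -0.056, 72.0, 0.0, 0.0, 0.0, 0.0),
    ("h", "alpha"): (0.126, -0.25, 77.0, 0.0, 0.0, 0.0, 0.0),
    ("h", "beta"): (1.7, 0.0, 22.5, 0.0, 0.0, -0.082, 1.0),
    ("j", "alpha"): (0.055, -0.25, 78.0, 0.0, 0.0, -0.2, 1.0),
    ("j", "beta"): (0.3, 0.0, 32.0, 0.0, 0.0, -0.1, 1.0),
    ("d", "alpha"): (0.095, -0.01, -5.0, 0.0, 0.0, -0.072, 1.0),
    ("d", "beta"): (0.07, -0.017, 44.0, 0.0, 0.0, 0.05, 1.0),
    ("f", "alpha"): (0.012, -0.008, 28.0, 0.0, 0.0, 0.15, 1.0),
    ("f", "beta"): (0.0065, -0.02, 30.0, 0.0, 0.0, -0.2, 1.0),
    ("x1", "alpha"): (0.0005, 0.083, 50.0, 0.0, 0.0, 0.057, 1.0),
    ("x1", "beta"): (0.0013, -0.06, 20.0, 0.0, 0.0, -0.04, 1.0),
}


@dataclass
class BRState:
    """Membrane potential (mV), six gates in [0,1], intracellular Ca (M)."""

    v: float = -84.57
    m: float = 0.011
    h: float = 0.988
    j: float = 0.975
    d: float = 0.003
    f: float = 0.994
    x1: float = 0.0001
    cai: float = 1.8e-7

    def as_vector(self) -> np.ndarray:
        return np.array([self.v, self.m, self.h, self.j, self.d, self.f, self.x1, self.cai])

    @classmethod
    def from_vector(cls, y) -> "BRState":
        return cls(*[float(x) for x in y])


def _rate(c: Tuple[float, ...], v: float) -> float:
    c1, c2, c3, c4, c5, c6, c7 = c
    num = 0.0
    if c1 != 0.0:
        num += c1 * math.exp(c2 * (v + c3))
    if c4 != 0.0:
        num += c4 * (v + c5)
    den = math.exp(c6 * (v + c3)) + c7
    if abs(den) < 1e-12:
        # removable singularity: num ~ c4*x, den ~ c6*x about the zero
        # (only the alpha_m entry reaches this point, at v = -c3)
        return c4 / c6
    return num / den


def rate_constants(gate: str, v: float) -> Tuple[float, float]:
    """(alpha, beta) in 1/ms for one gate at membrane potential v (mV)."""
    if gate not in BR_GATES:
        raise ValueError(f"unknown gate {gate!r}")
    if not math.isfinite(v):
        raise ValueError("non-finite membrane potential")
    a = _rate(_RATE_TABLE[(gate, "alpha")], v)
    b = _rate(_RATE_TABLE[(gate, "beta")], v)
    return max(a, 0.0), max(b, 0.0)


def gate_steady_state(gate: str, v: float) -> float:
    """Voltage-clamp steady state alpha/(alpha+beta), in [0, 1]."""
    a, b = rate_constants(gate, v)
    if a + b == 0.0:
        return 0.0
    return a / (a + b)


def ionic_currents(state: BRState) -> dict:
    """The four BR membrane currents (uA/cm^2) at the given state."""
    v = state.v
    i_na = (G_NA * state.m**3 * state.h * state.j + G_NAC) * (v - E_NA)
    e_s = -82.3 - 13.0287 * math.log(max(state.cai, 1e-12))
    i_s = G_S * state.d * state.f * (v - e_s)
    i_k1 = 0.35 * (
        4.0 * (math.exp(0.04 * (v + 85.0)) - 1.0)
        / (math.exp(0.08 * (v + 53.0)) + math.exp(0.04 * (v + 53.0)))
        + 0.2 * _k1_linear_term(v)
    )
    i_x1 = state.x1 * 0.8 * (math.exp(0.04 * (v + 77.0)) - 1.0) / math.exp(0.04 * (v + 35.0))
    return {"i_na": i_na, "i_s": i_s, "i_k1": i_k1, "i_x1": i_x1}


def _k1_linear_term(v: float) -> float:
    x = v + 23.0
    d = 1.0 - math.exp(-0.04 * x)
    if abs(d) < 1e-9:
        return 1.0 / 0.04  # limit of x / (1 - exp(-0.04 x)) as x -> 0
    return x / d


def br_derivatives(state: BRState, i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of [v, m, h, j, d, f, x1, cai]; t in ms."""
    y = state.as_vector()
    if not np.all(np.isfinite(y)) or not math.isfinite(i_stim):
        raise ValueError("non-finite state or stimulus")
    cur = ionic_currents(state)
    i_ion = cur["i_na"] + cur["i_s"] + cur["i_k1"] + cur["i_x1"]
    dv = (i_stim - i_ion) / C_M
    out = [dv]
    for gate in BR_GATES:
        g = getattr(state, gate)
        a, b = rate_constants(gate, state.v)
        out.append(a * (1.0 - g) - b * g)
    dcai = -1e-7 * cur["i_s"] + 0.07 * (1e-7 - state.cai)
    out.append(dcai)
    return np.array(out)


def find_rest(duration_ms: float = 20000.0) -> BRState:
    """Resting steady state by long relaxation plus fixed-point polish."""
    y0 = BRState().as_vector()
    fun = lambda t, y: br_derivatives(BRState.from_vector(y))
    sol = solve_ivp(fun, (0.0, duration_ms), y0, method="BDF", rtol=1e-8, atol=1e-10)
    y = sol.y[:, -1]
    res = root(lambda yy: br_derivatives(BRState.from_vector(yy)), y, method="lm", tol=1e-14)
    if res.success and np.all(np.isfinite(res.x)):
        y = res.x
    return BRState.from_vector(y)


_BR_REST: Optional[BRState] = None


def br_simulate(
    protocol: Optional[StimulusProtocol] = None,
    duration: float = 0.6,
    sample_dt: float = 0.5e-3,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trace:
    """Integrate the BR model from rest; times in s, voltages in mV.

    The default stimulus is a 30 uA/cm^2, 2 ms pulse at t = 50 ms.  The
    result reuses the Trace container: ``v_mem`` holds V (mV) and the
    current columns hold I_Na and I_K1 + I_x1 (uA/cm^2).
    """
    global _BR_REST
    if protocol is None:
        protocol = StimulusProtocol(pulses=(Pulse(0.05, 30.0, 0.002),))
    if _BR_REST is None:
        _BR_REST = find_rest()
    y = _BR_REST.as_vector()

    n = int(round(duration / sample_dt)) + 1
    t_grid = np.arange(n) * sample_dt
    ys = np.empty((8, n))
    ys[:, 0] = y
    # protocol times are in s and amplitudes in uA/cm^2; BR time unit is ms
    fun = lambda t, yy: br_derivatives(BRState.from_vector(yy), protocol.i_in(t * 1e-3))
    filled = 1
    for (a, b, active) in protocol.active_segments(duration):
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12)
        t_eval = np.clip(t_grid[mask], a, b) * 1e3
        sol = solve_ivp(
            fun,
            (a * 1e3, b * 1e3),
            y,
            method="BDF",
            rtol=rtol,
            atol=atol,
            max_step=(0.5 if active else 50.0),
            t_eval=t_eval if t_eval.size else None,
        )
        if not sol.success:
            raise RuntimeError(f"BR solver failed: {sol.message}")
        if t_eval.size:
            ys[:, filled : filled + t_eval.size] = sol.y[:, : t_eval.size]
            filled += t_eval.size
        y = sol.y[:, -1]
    ys = ys[:, :filled]
    t_grid = t_grid[:filled]

    i_na = np.empty(filled)
    i_out = np.empty(filled)
    for k in range(filled):
        cur = ionic_currents(BRState.from_vector(ys[:, k]))
        i_na[k] = -cur["i_na"]          # inward as positive, mirroring i_naca
        i_out[k] = cur["i_k1"] + cur["i_x1"]
    return Trace(
        t=t_grid,
        v_mem=ys[0],
        v_s=np.zeros(filled),
        v_gk=np.zeros(filled),
        i_naca=i_na,
        i_k=i_out,
        i_in=np.array([protocol.i_in(t) for t in t_grid]),
        meta={"model": "beeler-reuter-1977", "units": {"v": "mV", "i": "uA/cm^2"}},
    )


def br_ap_config(protocol: Optional[StimulusProtocol] = None) -> APConfig:
    """Feature-extraction config scaled to the BR model's mV units."""
    onset, end = 0.05, 0.052
    if protocol is not None and protocol.pulses:
        onset = protocol.pulses[0].t0
        end = onset + protocol.pulses[0].width
    return APConfig(
        stim_onset=onset,
        stim_end=end,
        plateau_band=15.0,
        notch_min_depth=5.0,
        dvdt_slow=500.0,
        min_amplitude=20.0,
        regen_rise=5.0,
        analysis_window=1.0,
        passive_slope=3.0e4,  # 30 uA/cm^2 on 1 uF/cm^2, in mV/s
    )


def compare_phases(
    oecm_trace: Trace,
    br_trace: Trace,
    oecm_config: APConfig,
    br_config: Optional[APConfig] = None,
) -> dict:
    """Per-phase durations and normalized amplitudes for the two models.

    Returns {'oecm': {...}, 'br': {...}} where each entry maps phase id to
    duration (s) and carries the normalized (0-1) plateau and peak levels;
    phases missing from a trace are reported as None.
    """
    if br_config is None:
        br_config = br_ap_config()
    out = {}
    for name, tr, cfg in (("oecm", oecm_trace, oecm_config), ("br", br_trace, br_config)):
        f = extract(tr, cfg)
        entry = {"phase_durations": {}, "amplitude": f.amplitude}
        for ph in range(5):
            if ph in f.phases:
                a, b = f.phases[ph]
                entry["phase_durations"][ph] = b - a
            else:
                entry["phase_durations"][ph] = None
        if f.amplitude and f.amplitude > 0 and f.plateau_level is not None:
            entry["plateau_level_norm"] = (f.plateau_level - f.v_rest) / f.amplitude
        else:
            entry["plateau_level_norm"] = None
        entry["cls"] = f.cls
        out[name] = entry
    return out
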