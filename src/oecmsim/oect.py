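"""Compact models of single organic electrochemical transistors (OECTs).

An OECT is a transistor whose channel conductance is modulated volumetrically
by ions injected from a gating electrolyte.  For circuit simulation we use an
accumulation-mode square-law compact model (Bernards-style): the drain current
is a triode/saturation quadratic in the gate overdrive, with a smooth
softplus subthreshold floor and an ohmic off-state leakage.  The electrolyte
enters through three calibrated laws:

* transconductance scales with ionic strength of the gating electrolyte
  (power law in concentration, normalized at the physiological reference);
* the threshold voltage rises Nernst-like as the electrolyte is diluted;
* the ion-doping (turn-on) time constant slows at low concentration.

Ladder-type (BBL) n-channels are additionally inhibited by protonation at
acidic pH, modelled as a Hill-type inhibition of the conductance factor.

Gate-coupling kinetics are represented by a first-order "doping state": an
effective internal gate drive that relaxes exponentially toward the applied
gate-source voltage with the electrolyte-dependent time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


__all__ = [
    "Polarity",
    "Role",
    "OECTParams",
    "ElectrolyteCondition",
    "DopingState",
    "drain_current",
    "conductance_factor",
    "threshold_voltage",
    "switching_time",
    "step_doping",
]

#: width (V) of the smooth subthreshold transition of the square law
SUBTHRESHOLD_WIDTH = 0.010

#: reference concentrations (mM) at which electrolyte factors normalize to 1
C_REF_KCL = 5.0     # physiological extracellular K+
C_REF_NACL = 140.0  # physiological extracellular Na+

#: concentration (mM) at which v_th_ref is defined (concentrated reference)
C_VTH_REF = 140.0

REFERENCE_PH = 7.0


class Polarity(str, Enum):
    n = "n"
    p = "p"


class Role(str, Enum):
    """Which circuit block an electrolyte factor is computed for."""

    K_channel = "K_channel"
    NaCa_channel = "NaCa_channel"
    S_inverter = "S_inverter"


@dataclass(frozen=True)
class OECTParams:
    """Compact-model parameters of one OECT.

    beta lumps W*d*mu*C*/L (A/V^2); v_th_ref is the threshold voltage at the
    concentrated reference electrolyte (140 mM); tau_* are doping time
    constants at the device's own reference electrolyte.
    """

    name: str
    polarity: Polarity
    beta: float            # A/V^2
    v_th_ref: float        # V, at C_VTH_REF
    g_off: float           # S, off-state leakage conductance
    tau_on_ref: float      # s, at the device's reference electrolyte
    tau_off_ref: float     # s
    lam: float = 0.0       # 1/V, channel-length-modulation (output conductance)
    ph_sensitive: bool = False   # BBL channels are protonation-inhibited
    geometry: Optional[dict] = None  # metadata only: W, L, d

    def __post_init__(self) -> None:
        if not (self.beta > 0):
            raise ValueError(f"{self.name}: beta must be > 0")
        if self.g_off < 0:
            raise ValueError(f"{self.name}: g_off must be >= 0")
        if not (self.tau_on_ref > 0 and self.tau_off_ref > 0):
            raise ValueError(f"{self.name}: time constants must be > 0")
        if self.lam < 0:
            raise ValueError(f"{self.name}: lam must be >= 0")
        if self.polarity not in (Polarity.n, Polarity.p):
            raise ValueError(f"{self.name}: polarity must be 'n' or 'p'")


@dataclass(frozen=True)
class ElectrolyteCondition:
    """State of a gating electrolyte: NaCl / KCl concentrations (mM) and pH."""

    nacl_mM: float = C_REF_NACL
    kcl_mM: float = C_REF_KCL
    ph: float = REFERENCE_PH

    def __post_init__(self) -> None:
        if self.nacl_mM < 0 or self.kcl_mM < 0:
            raise ValueError("concentrations must be >= 0")
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError("pH must be within [0, 14]")

    def concentration_for(self, role: Role) -> float:
        """Governing ion concentration (mM) for a circuit role."""
        return self.kcl_mM if role is Role.K_channel else self.nacl_mM


@dataclass(frozen=True)
class DopingState:
    """Effective internal gate drive (V) lagging the applied gate voltage."""

    s: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.s):
            raise ValueError("doping state must be finite")


def _smooth_overdrive(u_raw: float, width: float = SUBTHRESHOLD_WIDTH) -> float:
    """Softplus-smoothed overdrive: ~0 deep below threshold, ~u_raw above."""
    x = u_raw / width
    if x > 40.0:
        return u_raw
    if x < -40.0:
        return 0.0
    return width * math.log1p(math.exp(x))


def drain_current(
    params: OECTParams,
    v_gs_eff: float,
    v_ds: float,
    g_factor: float = 1.0,
    v_th: Optional[float] = None,
) -> float:
    """Drain current (A) of the square-law compact model.

    ``v_gs_eff`` is the effective (doping-lagged) gate-source voltage.  The
    threshold defaults to ``params.v_th_ref``; pass ``v_th`` (e.g. from
    :func:`threshold_voltage`) to use an electrolyte-shifted value.

    Sign convention: the returned value is the conventional current flowing
    from drain to source through the channel; it is antisymmetric in v_ds,
    zero channel current at v_ds = 0, and includes the ohmic leakage
    ``g_off * v_ds``.
    """
    if not (
        math.isfinite(v_gs_eff) and math.isfinite(v_ds) and math.isfinite(g_factor)
    ):
        raise ValueError("non-finite input to drain_current")
    if not g_factor > 0:
        raise ValueError("g_factor must be > 0")

    if v_th is None:
        v_th = params.v_th_ref
    sigma = 1.0 if params.polarity is Polarity.n else -1.0
    u = _smooth_overdrive(sigma * (v_gs_eff - v_th))
    x = sigma * v_ds  # signed drain-source voltage in the conduction sense
    ax = abs(x)
    if ax < u:  # triode
        i_mag = params.beta * (u - 0.5 * ax) * ax * (1.0 + params.lam * ax)
    else:  # saturation (C1 continuation with output conductance)
        i_mag = 0.5 * params.beta * u * u * (1.0 + params.lam * ax)
    i_ch = g_factor * math.copysign(i_mag, x) * sigma
    return i_ch + params.g_off * v_ds


def _ion_term(c_mM: float, c_ref: float, gamma: float) -> float:
    if c_mM <= 0:
        raise ValueError("zero or negative concentration: no ionic gating possible")
    return (c_mM / c_ref) ** gamma


def _ph_term(ph: float, pka: float, hill: float) -> float:
    """Hill-type protonation inhibition, normalized to 1 at pH 7.0."""
    h = 10.0 ** (-ph)
    ka = 10.0 ** (-pka)
    h_ref = 10.0 ** (-REFERENCE_PH)
    raw = 1.0 / (1.0 + (h / ka) ** hill)
    norm = 1.0 / (1.0 + (h_ref / ka) ** hill)
    return raw / norm


def conductance_factor(
    electrolyte: ElectrolyteCondition,
    role: Role,
    *,
    gamma: float = 0.35,
    pka: float = 6.3,
    hill: float = 2.0,
) -> float:
    """Dimensionless conductance multiplier for a circuit block.

    Product of a power-law ionic-strength term normalized to 1 at the
    physiological reference (5 mM KCl for the K channel, 140 mM NaCl
    otherwise) and, for BBL-containing roles, a Hill-type protonation
    inhibition normalized to 1 at pH 7.0.  All three roles contain a BBL
    n-channel, so the pH term always applies at the role level.
    """
    role = Role(role)
    c_ref = C_REF_KCL if role is Role.K_channel else C_REF_NACL
    c = electrolyte.concentration_for(role)
    return _ion_term(c, c_ref, gamma) * _ph_term(electrolyte.ph, pka, hill)


def threshold_voltage(
    params: OECTParams,
    electrolyte: ElectrolyteCondition,
    *,
    role: Role = Role.K_channel,
    kappa: float = 0.005,
) -> float:
    """Threshold voltage (V) at the given electrolyte condition.

    Nernst-like dilution shift: V_th = v_th_ref - kappa * ln(c / 140 mM), so
    a dilute electrolyte raises the threshold.  The default kappa places the
    5 mM KCl BBL threshold at 0.29 V for v_th_ref = 0.2733 V.
    """
    role = Role(role)
    c = electrolyte.concentration_for(role)
    if c <= 0:
        raise ValueError("zero concentration: no gating possible")
    return params.v_th_ref - kappa * math.log(c / C_VTH_REF)


def switching_time(
    params: OECTParams,
    electrolyte: ElectrolyteCondition,
    direction: str = "on",
    *,
    role: Role = Role.NaCa_channel,
    delta: float = 1.0,
) -> float:
    """Doping time constant (s), slower at lower electrolyte concentration.

    tau(c) = tau_ref * (c_device_ref / c)**delta where c_device_ref is the
    concentration at which tau_*_ref is quoted (the role's physiological
    reference).
    """
    role = Role(role)
    c_ref = C_REF_KCL if role is Role.K_channel else C_REF_NACL
    c = electrolyte.concentration_for(role)
    if c <= 0:
        raise ValueError("zero concentration: no gating possible")
    if direction == "on":
        tau_ref = params.tau_on_ref
    elif direction == "off":
        tau_ref = params.tau_off_ref
    else:
        raise ValueError("direction must be 'on' or 'off'")
    return tau_ref * (c_ref / c) ** delta


def step_doping(state: DopingState, v_gs_applied: float, dt: float, tau: float) -> DopingState:
    """Exact first-order relaxation of the doping state over one step.

    s' = v + (s - v) * exp(-dt / tau), the closed-form solution of
    ds/dt = (v - s) / tau over a constant-input interval.
    """
    if not (math.isfinite(v_gs_applied) and math.isfinite(dt)):
        raise ValueError("non-finite input to step_doping")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not tau > 0:
        raise ValueError("tau must be > 0")
    s_new = v_gs_applied + (state.s - v_gs_applied) * math.exp(-dt / tau)
    return replace(state, s=s_new)
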