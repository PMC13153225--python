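"""Stimulation waveform specifications.

A :class:`StimulusProtocol` describes the input current injected at the
membrane node: a list of square current pulses, a DC drive, or (for the
biohybrid mode) an externally recorded gate-voltage trace that replaces the
sensing inverter's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["Pulse", "StimulusProtocol"]


@dataclass(frozen=True)
class Pulse:
    """One square current pulse: onset time (s), amplitude (A), width (s)."""

    t0: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.t0)
            and math.isfinite(self.amplitude)
            and math.isfinite(self.width)
        ):
            raise ValueError("pulse fields must be finite")
        if self.width < 0:
            raise ValueError("pulse width must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Input drive for the membrane node.

    mode 'pulses': square pulses, non-overlapping and time-ordered.
    mode 'dc': constant current of ``dc_amplitude``.
    mode 'external_gate': no input current; ``external`` is a (t, v) pair of
    arrays giving the recorded gate drive that substitutes for the sensing
    inverter's output.
    """

    mode: str = "pulses"
    pulses: Tuple[Pulse, ...] = ()
    dc_amplitude: float = 0.0
    external: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("pulses", "dc", "external_gate"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        pulses = tuple(
            p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses
        )
        object.__setattr__(self, "pulses", pulses)
        for a, b in zip(pulses, pulses[1:]):
            if b.t0 < a.t0 + a.width:
                raise ValueError("pulses must be time-ordered and non-overlapping")
        if self.mode == "external_gate":
            if self.external is None:
                raise ValueError("external_gate mode requires an external trace")
            t, v = self.external
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 2:
                raise ValueError("external trace must be two equal 1-d arrays")
            if not np.all(np.diff(t) > 0):
                raise ValueError("external trace times must be increasing")
            object.__setattr__(self, "external", (t, v))

    def i_in(self, t: float) -> float:
        """Input current (A) at time t."""
        if self.mode == "dc":
            return self.dc_amplitude
        if self.mode == "external_gate":
            return 0.0
        for p in self.pulses:
            if p.t0 <= t < p.t0 + p.width:
                return p.amplitude
        return 0.0

    def segment_edges(self, duration: float) -> np.ndarray:
        """Time points where the drive is discontinuous, within [0, duration]."""
        edges = {0.0, float(duration)}
        if self.mode == "pulses":
            for p in self.pulses:
                for e in (p.t0, p.t0 + p.width):
                    if 0.0 < e < duration:
                        edges.add(float(e))
        return np.array(sorted(edges))

    def active_segments(self, duration: float) -> list:
        """(t_start, t_end, active) tuples; 'active' marks pulse intervals."""
        edges = self.segment_edges(duration)
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            active = self.mode == "dc" or self.i_in(mid) != 0.0
            out.append((float(a), float(b), bool(active)))
        return out

    def shifted(self, dt: float) -> "StimulusProtocol":
        """Protocol translated in time by dt (pulses mode only)."""
        if self.mode != "pulses":
            raise ValueError("time shift only defined for pulse protocols")
        return StimulusProtocol(
            mode="pulses",
            pulses=tuple(Pulse(p.t0 + dt, p.amplitude, p.width) for p in self.pulses),
        )
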