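"""Feature extraction on constructed signals with known landmarks."""

import numpy as np
import pytest

from oecmsim.circuit import Trace
from oecmsim.features import (
    APConfig,
    ClassifyThresholds,
    classify_response,
    extract,
)

DT = 0.5e-3


def make_trace(v, dt=DT):
    v = np.asarray(v, dtype=float)
    t = np.arange(len(v)) * dt
    z = np.zeros_like(v)
    return Trace(t=t, v_mem=v, v_s=z, v_gk=z.copy(), i_naca=z.copy(),
                 i_k=z.copy(), i_in=z.copy())


def trapezoid(rest=0.0, level=0.3, rise_ms=10, flat_ms=200, fall_ms=50,
              lead_ms=50, tail_ms=300):
    seg = []
    seg.append(np.full(int(lead_ms / 0.5), rest))
    seg.append(np.linspace(rest, level, int(rise_ms / 0.5), endpoint=False))
    seg.append(np.full(int(flat_ms / 0.5), level))
    seg.append(np.linspace(level, rest, int(fall_ms / 0.5), endpoint=False))
    seg.append(np.full(int(tail_ms / 0.5), rest))
    return np.concatenate(seg)


class TestConstructedSignals:
    def test_trapezoid_plateau_duration_exact(self):
        tr = make_trace(trapezoid())
        cfg = APConfig(stim_onset=0.05, stim_end=0.06, plateau_band=0.03)
        f = extract(tr, cfg)
        # the flat stretch is 200 ms; band entry/exit adds at most the
        # rise/fall samples within +/-0.03 V of the level
        slack = (0.03 / 0.3) * (10e-3 + 50e-3) + 2 * DT
        assert f.plateau_duration == pytest.approx(200e-3, abs=slack)
        assert f.plateau_level == pytest.approx(0.3, abs=1e-6)

    def test_flat_trace_is_none(self):
        tr = make_trace(np.full(2000, 0.1))
        f = extract(tr, APConfig(stim_onset=0.05, stim_end=0.07))
        assert f.cls == "none"
        assert f.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_notch_detected_on_spike_then_plateau(self):
        # peak 0.4, dip to 0.25, then 150 ms plateau at 0.3
        v = np.concatenate([
            np.full(100, 0.0),
            np.linspace(0.0, 0.4, 30),
            np.linspace(0.4, 0.25, 30),
            np.linspace(0.25, 0.3, 20),
            np.full(300, 0.3),
            np.linspace(0.3, 0.0, 60),
            np.full(400, 0.0),
        ])
        f = extract(make_trace(v), APConfig(stim_onset=0.05, stim_end=0.06))
        assert f.notch_min == pytest.approx(0.25, abs=0.01)
        assert f.v_peak == pytest.approx(0.4)
        assert f.plateau_level == pytest.approx(0.3, abs=0.01)

    def test_time_offset_invariance(self):
        v = trapezoid()
        f1 = extract(make_trace(v), APConfig(stim_onset=0.05, stim_end=0.06))
        tr2 = make_trace(v)
        tr2.t = tr2.t + 1.234  # same waveform, shifted clock
        tr2 = Trace(t=tr2.t - tr2.t[0], v_mem=tr2.v_mem, v_s=tr2.v_s,
                    v_gk=tr2.v_gk, i_naca=tr2.i_naca, i_k=tr2.i_k,
                    i_in=tr2.i_in)
        f2 = extract(tr2, APConfig(stim_onset=0.05, stim_end=0.06))
        assert f1.plateau_duration == pytest.approx(f2.plateau_duration)
        assert f1.amplitude == pytest.approx(f2.amplitude)

    def test_voltage_offset_invariance(self):
        v = trapezoid()
        f1 = extract(make_trace(v), APConfig(stim_onset=0.05, stim_end=0.06))
        f2 = extract(make_trace(v + 0.05), APConfig(stim_onset=0.05, stim_end=0.06))
        assert f2.amplitude == pytest.approx(f1.amplitude)
        assert f2.plateau_duration == pytest.approx(f1.plateau_duration)
        assert f2.v_rest == pytest.approx(f1.v_rest + 0.05)

    def test_apd50_on_trapezoid(self):
        tr = make_trace(trapezoid())
        f = extract(tr, APConfig(stim_onset=0.05, stim_end=0.06))
        # crossing at 0.15 V: halfway up the rise and halfway down the fall
        expected = 5e-3 + 200e-3 + 25e-3
        assert f.apd == pytest.approx(expected, abs=2 * DT)

    def test_non_uniform_trace_rejected(self):
        tr = make_trace(trapezoid())
        t_bad = tr.t.copy()
        t_bad[10] += 1e-4
        with pytest.raises(ValueError):
            Trace(t=t_bad, v_mem=tr.v_mem, v_s=tr.v_s, v_gk=tr.v_gk,
                  i_naca=tr.i_naca, i_k=tr.i_k, i_in=tr.i_in)


class TestClassification:
    def full_features(self):
        tr = make_trace(trapezoid())
        return extract(tr, APConfig(stim_onset=0.05, stim_end=0.055))

    def test_identity_is_full(self):
        ref = self.full_features()
        assert classify_response(ref, ref) == "full"

    def test_zero_amplitude_is_none(self):
        ref = self.full_features()
        flat = extract(make_trace(np.zeros(2000)),
                       APConfig(stim_onset=0.05, stim_end=0.06))
        assert classify_response(flat, ref) == "none"

    def test_premature_rule(self):
        ref = self.full_features()
        # 60 % amplitude spike with no plateau
        v = np.concatenate([
            np.full(100, 0.0),
            np.linspace(0.0, 0.18, 20),
            np.linspace(0.18, 0.0, 80),
            np.full(1000, 0.0),
        ])
        f = extract(make_trace(v), APConfig(stim_onset=0.05, stim_end=0.055,
                                            plateau_level_hint=ref.plateau_level))
        assert classify_response(f, ref) == "premature"

    def test_sustained_rule(self):
        ref = self.full_features()
        v = np.concatenate([
            np.full(100, 0.0),
            np.linspace(0.0, 0.3, 30),
            np.full(4000, 0.3),
        ])
        f = extract(make_trace(v), APConfig(stim_onset=0.05, stim_end=0.06,
                                            analysis_window=1.5))
        assert classify_response(f, ref) == "sustained_depolarization"

    def test_subthreshold_rule(self):
        ref = self.full_features()
        # passive charge-and-decay bump: never rises after the stimulus ends
        t = np.arange(2000) * DT
        v = np.where(t < 0.05, 0.0, 0.06 * np.exp(-(t - 0.05) / 0.05))
        v[(t >= 0.03) & (t < 0.05)] = np.linspace(0, 0.06, 40)
        f = extract(make_trace(v), APConfig(stim_onset=0.03, stim_end=0.05,
                                            passive_slope=3.0))
        assert classify_response(f, ref) == "subthreshold"
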