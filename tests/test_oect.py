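"""Unit tests for the OECT compact model and its electrolyte laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oecmsim.oect import (
    DopingState,
    ElectrolyteCondition,
    OECTParams,
    Polarity,
    Role,
    conductance_factor,
    drain_current,
    step_doping,
    switching_time,
    threshold_voltage,
)


def n_device(**kw):
    base = dict(
        name="n", polarity=Polarity.n, beta=1e-3, v_th_ref=0.29,
        g_off=1e-7, tau_on_ref=1e-3, tau_off_ref=1e-3, lam=0.0,
    )
    base.update(kw)
    return OECTParams(**base)


class TestDrainCurrent:
    def test_zero_bias_zero_current(self):
        dev = n_device(g_off=0.0)
        for vgs in (-0.5, 0.0, 0.29, 1.0):
            assert drain_current(dev, vgs, 0.0) == 0.0

    def test_saturation_square_law(self):
        # beta/2 * u^2 with u = 0.2 V overdrive -> 20 uA (plus ~nothing:
        # the softplus correction at 20x the transition width is negligible)
        dev = n_device(beta=1e-3, v_th_ref=0.29, g_off=0.0)
        i = drain_current(dev, 0.49, 0.6)
        assert i == pytest.approx(20e-6, rel=1e-4)

    def test_deep_subthreshold_is_leakage_floor(self):
        dev = n_device(g_off=1e-7)
        i = drain_current(dev, -0.5, 0.6)
        assert i == pytest.approx(1e-7 * 0.6, rel=1e-3)

    def test_antisymmetric_in_vds(self):
        dev = n_device(g_off=5e-8)
        i_fwd = drain_current(dev, 0.5, 0.3)
        i_rev = drain_current(dev, 0.5, -0.3)
        assert i_rev == pytest.approx(-i_fwd)

    def test_p_type_sign_convention(self):
        # p device sourced high: gate below source turns it on, current
        # flows source->drain, i.e. negative drain current for v_ds < 0
        dev = OECTParams(
            name="p", polarity=Polarity.p, beta=1e-3, v_th_ref=-0.2,
            g_off=0.0, tau_on_ref=1e-3, tau_off_ref=1e-3,
        )
        i = drain_current(dev, -0.5, -0.4)
        assert i < 0

    def test_rejects_non_finite(self):
        dev = n_device()
        with pytest.raises(ValueError):
            drain_current(dev, float("nan"), 0.1)
        with pytest.raises(ValueError):
            drain_current(dev, 0.1, 0.1, g_factor=0.0)

    @given(st.floats(-0.5, 1.0), st.floats(-0.5, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_overdrive(self, vgs_a, vgs_b):
        dev = n_device(g_off=0.0)
        lo, hi = sorted((vgs_a, vgs_b))
        assert drain_current(dev, lo, 0.5) <= drain_current(dev, hi, 0.5) + 1e-18

    def test_continuity_across_triode_saturation(self):
        dev = n_device(v_th_ref=0.0, lam=1.5, g_off=0.0)
        u = 0.2
        vds = np.linspace(0.0, 0.6, 2001)
        i = np.array([drain_current(dev, u, x) for x in vds])
        # no jumps in value or first difference
        di = np.diff(i)
        assert np.all(np.abs(np.diff(di)) < 5e-7)


class TestElectrolyteLaws:
    def test_conductance_reference_normalization(self):
        e = ElectrolyteCondition(kcl_mM=5.0, ph=7.0)
        assert conductance_factor(e, Role.K_channel) == pytest.approx(1.0)
        e2 = ElectrolyteCondition(nacl_mM=140.0, ph=7.0)
        assert conductance_factor(e2, Role.NaCa_channel) == pytest.approx(1.0)

    def test_conductance_increases_with_concentration(self):
        f = lambda c: conductance_factor(
            ElectrolyteCondition(kcl_mM=c), Role.K_channel
        )
        assert f(15.0) > f(7.5) > 1.0 > f(3.0) > f(1.5)

    def test_acidification_inhibits(self):
        f = lambda ph: conductance_factor(
            ElectrolyteCondition(kcl_mM=5.0, ph=ph), Role.K_channel
        )
        assert f(7.0) == pytest.approx(1.0)
        assert 1.0 > f(6.5) > f(6.0) > 0.0

    def test_zero_concentration_rejected(self):
        e = ElectrolyteCondition(kcl_mM=0.0)
        with pytest.raises(ValueError):
            conductance_factor(e, Role.K_channel)
        with pytest.raises(ValueError):
            threshold_voltage(n_device(), e, role=Role.K_channel)
        with pytest.raises(ValueError):
            switching_time(n_device(), e, role=Role.K_channel)

    def test_threshold_dilution_calibration_point(self):
        # BBL K-channel device: 0.29 V at the physiological 5 mM KCl
        dev = n_device(v_th_ref=0.2733)
        e = ElectrolyteCondition(kcl_mM=5.0)
        assert threshold_voltage(dev, e, role=Role.K_channel) == pytest.approx(
            0.29, abs=0.005
        )
        # at the concentrated reference the shift vanishes
        e_ref = ElectrolyteCondition(kcl_mM=140.0)
        assert threshold_voltage(dev, e_ref, role=Role.K_channel) == pytest.approx(0.2733)

    def test_threshold_monotone_in_dilution(self):
        dev = n_device(v_th_ref=0.2733)
        vth = lambda c: threshold_voltage(
            dev, ElectrolyteCondition(kcl_mM=c), role=Role.K_channel
        )
        assert vth(1.5) > vth(5.0) > vth(15.0)

    def test_switching_time_calibration_points(self):
        from oecmsim.presets import paper2026

        p = paper2026()
        naca = p.oects["naca_n"]
        assert switching_time(
            naca, ElectrolyteCondition(nacl_mM=140.0), "on", role=Role.NaCa_channel
        ) == pytest.approx(0.17e-3)
        k = p.oects["k"]
        assert switching_time(
            k, ElectrolyteCondition(kcl_mM=5.0), "on", role=Role.K_channel
        ) == pytest.approx(16.2e-3)
        s = p.oects["s_n"]
        assert switching_time(
            s, ElectrolyteCondition(nacl_mM=140.0), "on", role=Role.S_inverter
        ) == pytest.approx(0.21e-3)

    def test_switching_slows_in_dilute_electrolyte(self):
        dev = n_device()
        tau = lambda c: switching_time(
            dev, ElectrolyteCondition(kcl_mM=c), "on", role=Role.K_channel
        )
        assert tau(1.5) > tau(5.0) > tau(15.0)


class TestDoping:
    def test_zero_dt_identity(self):
        s = DopingState(0.3)
        assert step_doping(s, 1.0, 0.0, 1e-3).s == pytest.approx(0.3)

    def test_long_time_fixed_point(self):
        s = DopingState(0.0)
        assert step_doping(s, 1.0, 10.0, 1e-3).s == pytest.approx(1.0)

    def test_one_tau_closed_form(self):
        s = DopingState(0.0)
        out = step_doping(s, 1.0, 1e-3, 1e-3)
        assert out.s == pytest.approx(1.0 - math.exp(-1.0))

    @given(
        st.floats(-1.0, 1.0),
        st.floats(-1.0, 1.0),
        st.floats(1e-4, 1e-1),
        st.floats(1e-4, 1e-1),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_fine_euler(self, s0, v, dt, tau):
        exact = step_doping(DopingState(s0), v, dt, tau).s
        # explicit Euler with step h has the closed form
        # s_n = v + (s0 - v) (1 - h/tau)^n; evaluate it at a very fine step
        n = 2**22
        h = dt / n
        euler = v + (s0 - v) * (1.0 - h / tau) ** n
        assert abs(euler - exact) < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            step_doping(DopingState(0.0), 1.0, -1e-3, 1e-3)
        with pytest.raises(ValueError):
            step_doping(DopingState(0.0), 1.0, 1e-3, 0.0)


def test_params_validation():
    with pytest.raises(ValueError):
        n_device(beta=0.0)
    with pytest.raises(ValueError):
        n_device(tau_on_ref=0.0)
    with pytest.raises(ValueError):
        ElectrolyteCondition(ph=15.0)
    with pytest.raises(ValueError):
        ElectrolyteCondition(nacl_mM=-1.0)
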