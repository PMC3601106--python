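"""Pyramidal cell: GHK flux, L-type channel, synapse kinetics."""

import math

import numpy as np
import pytest
import sympy

from ecbdsi import ModelParameters, IntegratorSettings, StimulusProgram, integrate
from ecbdsi.postsynaptic import (
    ghk_driving_force, l_type_current, gaba_synapse_rhs, ampa_alpha_train,
    resting_potential, pyramidal_rhs, traub_steady_gates,
)
from ecbdsi.stimulus import PulseTrain, SynapticTrain, make_fixture
from ecbdsi.params import FARADAY, GAS_CONSTANT


def _ghk_sympy(v_mv, ca_in_um, ca_out_um, t_k, digits=50):
    """Arbitrary-precision evaluation of the GHK flux factor."""
    v = sympy.Rational(v_mv) / 1000
    ci = sympy.Rational(ca_in_um) * sympy.Rational(1, 10**9)
    co = sympy.Rational(ca_out_um) * sympy.Rational(1, 10**9)
    z, f, r = sympy.Integer(2), sympy.Rational(96485), sympy.Rational(8314, 1000)
    x = z * f * v / (r * sympy.Rational(t_k))
    expr = z * f * (x / (1 - sympy.exp(-x))) * (ci - co * sympy.exp(-x))
    return float(sympy.N(expr, digits))


class TestGHK:
    def test_no_gradient_no_field(self):
        assert ghk_driving_force(0.0, 2000.0, 2000.0, 298.15) == pytest.approx(0.0, abs=1e-12)

    def test_removable_singularity_at_zero(self):
        # the series branch must agree with the analytic limit zF(ci - co)
        lim = 2 * FARADAY * (0.02e-9 - 2000e-9)
        assert ghk_driving_force(0.0, 0.02, 2000.0, 298.15) == pytest.approx(lim, rel=1e-10)
        # continuity across the branch switch at |V| = 1e-4 mV
        lo = ghk_driving_force(9.9e-5, 0.02, 2000.0, 298.15)
        hi = ghk_driving_force(1.01e-4, 0.02, 2000.0, 298.15)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_against_high_precision_oracle(self):
        for v in (-80.0, -20.0, 0.01, 30.0, 120.0):
            got = ghk_driving_force(v, 0.02, 2000.0, 298.15)
            want = _ghk_sympy(v, sympy.Rational(1, 50), 2000, sympy.Rational(29815, 100))
            assert got == pytest.approx(want, rel=1e-10)

    def test_inward_at_negative_voltage(self):
        assert ghk_driving_force(-80.0, 0.02, 2000.0, 298.15) < 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ghk_driving_force(0.0, -1.0, 2000.0, 298.15)


class TestLType:
    def test_closed_channels_carry_no_current(self, params):
        i, _, _ = l_type_current(-20.0, 0.0, 1.0, 0.02, params)
        assert i == 0.0

    def test_zero_permeability(self, params):
        p0 = params.replace(**{"postsynaptic.p_max_l": 0.0})
        i, _, _ = l_type_current(0.0, 0.5, 1.0, 0.02, p0)
        assert i == 0.0

    def test_inward_at_subzero_voltage(self, params):
        i, _, _ = l_type_current(-10.0, 0.5, 1.0, 0.02, params)
        assert i < 0.0  # outward-positive convention

    def test_charge_integral_converges_with_step_halving(self, params):
        # 1 s clamp to 0 mV; time-integral of I_Ca via the calcium trace
        prog = make_fixture("clamp_step", v_hold=0.0, duration=1.0, onset=0.2,
                            cell="post", v_base=-80.0, total=1.5)
        vals = {}
        for method in ("rk4", "reference"):
            s = IntegratorSettings(dt=0.02, record_dt=0.5, method=method)
            res = integrate(prog, params, s)
            vals[method] = res.trace("ca_c").max()
        assert vals["rk4"] == pytest.approx(vals["reference"], rel=1e-3)


class TestCellModel:
    def test_rest_is_fixed_point(self, params):
        v = resting_potential(params)
        m, h, n = traub_steady_gates(v, params.postsynaptic.v_t)
        from ecbdsi.postsynaptic import _ml_rates
        a, b = _ml_rates(v)
        post = params.postsynaptic
        h_l = 1.0 / (1.0 + math.exp((v - post.v_half_inact) / post.k_inact))
        dy = pyramidal_rhs([v, h, n, a / (a + b), h_l], params, ca_in=0.02)
        # voltage and HH gate derivatives vanish; the tiny residual on V is
        # the resting L-type window current
        assert abs(dy[0]) < 1e-4
        assert abs(dy[1]) < 1e-9 and abs(dy[2]) < 1e-9

    def test_suprathreshold_pulse_elicits_spiking(self, params):
        # the stated 25 uA/cm^2, 5 ms pulse is strongly suprathreshold;
        # spike count agrees with the half-step reference integration
        counts = {}
        for method in ("rk4", "reference"):
            prog = StimulusProgram(duration=0.3)
            prog.pulses.append(PulseTrain("post", 25.0, 5.0, 0.1))
            s = IntegratorSettings(dt=0.02, record_dt=0.05, method=method)
            res = integrate(prog, params, s)
            v = res.trace("v_post")
            counts[method] = int(np.sum((v[:-1] < 0) & (v[1:] >= 0)))
        assert counts["rk4"] >= 1
        assert counts["rk4"] == counts["reference"]

    def test_adjusted_pulse_single_spike(self, params):
        # a just-suprathreshold 5 ms pulse elicits exactly one action potential
        prog = StimulusProgram(duration=0.3)
        prog.pulses.append(PulseTrain("post", 6.5, 5.0, 0.1))
        s = IntegratorSettings(dt=0.02, record_dt=0.05)
        res = integrate(prog, params, s)
        v = res.trace("v_post")
        assert int(np.sum((v[:-1] < 0) & (v[1:] >= 0))) == 1

    def test_rejects_nan_state(self, params):
        with pytest.raises(ValueError):
            pyramidal_rhs([np.nan, 0.1, 0.1, 0.0, 1.0], params)


class TestGABASynapse:
    def test_near_silent_at_rest(self, params):
        # subthreshold presynaptic potential: drive ~ 0, so a bound fraction
        # well above the tiny standing level decays with tau ~ 1 ms
        ds, g = gaba_synapse_rhs(0.2, -64.0, 1.0, params)
        assert ds == pytest.approx(-0.2 / params.postsynaptic.tau_gaba, rel=0.05)
        assert g == pytest.approx(params.postsynaptic.g_gaba * 0.2)

    def test_omega_shift_is_monotone(self, params):
        # identical presynaptic depolarisation, increasing omega -> larger drive
        drives = [gaba_synapse_rhs(0.0, 0.0, w, params)[0]
                  for w in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b > a for a, b in zip(drives, drives[1:]))

    def test_peak_s_matches_half_step_reference(self, params):
        prog = StimulusProgram(duration=0.1)
        prog.hold("pre", -80.0)
        prog.clamp_pulse("pre", 0.0, 0.05, 2.0, measure=True)
        peaks = {}
        for method in ("rk4", "reference"):
            s = IntegratorSettings(dt=0.02, record_dt=0.5, method=method)
            res = integrate(prog, params, s)
            peaks[method] = res.event_amps[0]
        assert peaks["rk4"] == pytest.approx(peaks["reference"], rel=1e-6)


class TestAMPA:
    def test_no_events(self, params):
        t = np.linspace(0, 10, 100)
        assert np.all(ampa_alpha_train([], t, params) == 0.0)

    def test_alpha_peak_time_and_height(self, params):
        tau = params.postsynaptic.tau_ampa
        t = np.linspace(0, 20, 20001)
        s = ampa_alpha_train([5.0], t, params)
        assert t[np.argmax(s)] == pytest.approx(5.0 + tau, abs=2e-3)
        assert s.max() == pytest.approx(1.0, rel=1e-4)

    def test_unsorted_events_rejected(self, params):
        with pytest.raises(ValueError):
            ampa_alpha_train([3.0, 1.0], np.linspace(0, 5, 10), params)

    def test_synaptic_event_elicits_spike(self, params):
        # peak conductance 10 mS/cm^2 drives one action potential per event
        prog = StimulusProgram(duration=0.4)
        prog.synaptic.append(SynapticTrain(freq_hz=10.0, duration=0.15,
                                           onset=0.1))
        s = IntegratorSettings(dt=0.02, record_dt=0.05)
        res = integrate(prog, params, s)
        v = res.trace("v_post")
        assert int(np.sum((v[:-1] < 0) & (v[1:] >= 0))) == 2  # one per event
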