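"""Calcium/ER dynamics, DAG production, 2-AG synthesis and bookkeeping."""

import numpy as np
import pytest

from ecbdsi import ModelParameters, IntegratorSettings, StimulusProgram, integrate
from ecbdsi.signalling import (
    pump_flux, calcium_rhs, current_to_flux, dag_rhs, ag_rhs, basal_state,
)
from ecbdsi.stimulus import make_fixture
from ecbdsi.params import FARADAY


class TestPumpFlux:
    @pytest.mark.parametrize("c,vmax,k,expected", [
        (0.0, 1.0, 0.1, 0.0),
        (0.1, 1.0, 0.1, 0.5),        # half-activation at C = K
        (0.1, 0.0575, 0.1, 0.02875),  # SERCA half-activation constant 0.1
    ])
    def test_hill2_values(self, c, vmax, k, expected):
        assert pump_flux(c, vmax, k) == pytest.approx(expected)

    def test_monotone_saturating(self):
        c = np.linspace(0, 10, 50)
        f = np.array([pump_flux(x, 1.0, 0.12) for x in c])
        assert np.all(np.diff(f) >= 0) and f[-1] < 1.0


class TestCurrentToFlux:
    def test_zero_current(self):
        assert current_to_flux(0.0, 10.0, 0.01) == 0.0

    def test_linear_in_buffering(self):
        j1 = current_to_flux(-1.0, 10.0, 0.01)
        j2 = current_to_flux(-1.0, 10.0, 0.02)
        assert j2 == pytest.approx(2 * j1)

    def test_dimensional_analysis_oracle(self):
        # hand derivation for a 10 um sphere, beta = 0.01, I = -1 uA/cm^2:
        # S/V = 3/r = 3e3 cm^-1; mol flux = I/(zF) = 1e-6/(2*96485) mol/(s cm^2)
        # concentration rate = flux * S/V = 1.5546e-8 mol/(cm^3 s)
        #                    = 1.5546e1 uM/s; times beta -> 0.15546 uM/s
        expected = 0.01 * (1e-6 / (2 * FARADAY)) * 3e3 * 1e9
        assert current_to_flux(-1.0, 10.0, 0.01) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1554646, rel=1e-5)

    def test_sign_convention(self):
        # inward (negative) current -> positive influx
        assert current_to_flux(-1.0, 10.0, 0.01) > 0

    def test_invalid_radius(self):
        with pytest.raises(Exception):
            current_to_flux(1.0, -1.0, 0.01)


class TestCalcium:
    def test_basal_fixed_point_is_002(self, params):
        b = basal_state(params)
        assert b["ca_c"] == pytest.approx(0.02, rel=1e-6)
        dca, der = calcium_rhs(b["ca_c"], b["ca_er"], 0.0, params)
        assert abs(dca) < 1e-12 and abs(der) < 1e-12

    def test_leak_only_equilibrium(self, params):
        # pumps disabled, leak only: gradient decays to zero
        p0 = params.replace(**{"signalling.v_serca": 0.0,
                               "signalling.v_pmca": 0.0,
                               "signalling.nu0": 0.0})
        dca, der = calcium_rhs(0.5, 0.5, 0.0, p0)
        assert dca == 0.0 and der == 0.0
        dca, der = calcium_rhs(0.2, 1.0, 0.0, p0)
        assert dca > 0 and der < 0  # leak moves both toward equality

    def test_er_volume_ratio_bookkeeping(self, params):
        # what leaves the ER enters the cytosol scaled by rho
        rho = params.signalling.rho
        dca, der = calcium_rhs(0.02, 5.0, 0.0, params)
        dca0, _ = calcium_rhs(0.02, 0.02, 0.0, params)
        net_leak_to_cyt = dca - dca0
        assert der == pytest.approx(-net_leak_to_cyt / rho +
                                    calcium_rhs(0.02, 0.02, 0.0, params)[1],
                                    rel=1e-9)

    def test_free_evolution_settles_to_basal(self, params):
        prog = StimulusProgram(duration=60.0)
        prog.hold("post", -80.0)
        prog.hold("pre", -80.0)
        s = IntegratorSettings(dt=0.02, record_dt=5.0)
        res = integrate(prog, params, s)
        assert res.trace("ca_c")[-1] == pytest.approx(0.02, rel=0.10)
        assert res.trace("dag")[-1] < 0.05
        assert res.trace("ag")[-1] < 0.05


class TestDAG:
    def test_production_values(self, params):
        # half of V_dag = 10 at the half-activation constant 0.7 uM
        assert dag_rhs(0.0, 0.7, params=params) == pytest.approx(5.0)
        assert dag_rhs(0.0, 0.0, params=params) == 0.0
        # basal calcium: production negligible (direct Hill evaluation)
        basal = dag_rhs(0.0, 0.02, params=params)
        assert basal == pytest.approx(10 * 0.02**2 / (0.02**2 + 0.7**2), rel=1e-9)
        assert basal < 0.01


class TestAG:
    def test_rest(self, params):
        dag_dt, dp = ag_rhs(0.0, 0.0, 0.0, params)
        assert dag_dt == 0.0 and dp == 0.0

    def test_pool_ceiling_without_oxidation(self, params):
        p0 = params.replace(**{"signalling.cox2": 0.0})
        # synthesis shuts off as AG approaches the 50 uM ceiling
        d_lo, _ = ag_rhs(0.0, 0.0, 5.0, p0)
        d_hi, _ = ag_rhs(49.99, 0.0, 5.0, p0)
        assert d_lo > 0 and d_hi < d_lo and d_hi == pytest.approx(
            p0.signalling.k_syn * 5.0 * (1 - 49.99 / 50.0))

    def test_conservation_along_trajectory(self, params):
        """d(AG + P)/dt equals the synthesis inflow: along a depolarisation
        trajectory the integrated inflow matches AG + P to high accuracy."""
        prog = make_fixture("clamp_step", v_hold=0.0, duration=5.0, onset=1.0,
                            cell="post", v_base=-80.0, total=12.0)
        prog.hold("pre", -80.0)
        s = IntegratorSettings(dt=0.02, record_dt=0.5)
        res = integrate(prog, params, s)
        dag = res.trace("dag")
        ag = res.trace("ag")
        p = res.trace("p_ox")
        sig = params.signalling
        cap = 1.0 - (ag + p) / sig.ag_max
        inflow = sig.k_syn * dag * np.clip(cap, 0.0, None)  # uM/s
        total = np.trapezoid(inflow, res.t) + ag[0] + p[0]
        drift = abs((ag[-1] + p[-1]) - total) / max(ag[-1] + p[-1], 1e-12)
        assert drift < 1e-4


def test_calcium_decay_slower_than_peak_scale(params):
    """Peak calcium under a 5 s step is monotone in step duration."""
    peaks = []
    for dur in (0.5, 2.0, 5.0):
        prog = make_fixture("clamp_step", v_hold=0.0, duration=dur, onset=1.0,
                            cell="post", v_base=-80.0, total=8.0)
        prog.hold("pre", -80.0)
        s = IntegratorSettings(dt=0.02, record_dt=1.0)
        res = integrate(prog, params, s)
        peaks.append(res.trace("ca_c").max())
    assert peaks[0] < peaks[1] < peaks[2]
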