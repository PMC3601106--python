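"""Coupled-system assembly and fixed-step RK4 integration.

The full model is a 19-component ODE system integrated with classical RK4
on a single ms time base (default dt = 0.02 ms, resolving the HH spike; the
signalling variables are slow and impose no constraint).  The integrated
state follows the model's dynamic-variable table - presynaptic (V, h, n),
CB1 (omega, G, plus a low-pass filtered presynaptic voltage driving the
reluctant-to-willing rate), postsynaptic (V, h, n, m_L, h_L), signalling
(Ca_c, Ca_ER, DAG, AG) - plus the oxidation product P (for closed 2-AG
bookkeeping), the two bound-receptor fractions, and one auxiliary state
generating the AMPA alpha function.  Sodium activation gates are instantaneous on both cells and
are not integrated.

Stimuli are sample-and-hold step functions aligned to the integration grid:
within a step all drives are constant, so RK4 retains its order away from
the (grid-aligned) switching instants.  Voltage clamp is algebraic pinning:
the clamped potential is set to the holding value and its derivative zeroed,
while gates and concentrations evolve; on release the potential continues
from the held value.  Evoked IPSP amplitudes (per-event peak of the bound
GABA_A receptor fraction, onset-baseline subtracted) are tracked inside the
loop at full step resolution.

The model is fully deterministic: identical runs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._numba import njit
from . import params as P
from .params import (
    NSTATE, STATE_COLUMNS, IV_PRE, IH_PRE, IN_PRE, IOMEGA, IG,
    IVF_PRE, IV_POST, IH_POST, IN_POST, IM_L, IH_L, ICA_C, ICA_ER, IDAG, IAG, IP_OX,
    IS_GABA, IS_AMPA, IX_AMPA,
    ModelParameters, IntegratorSettings, pack_parameters,
    flux_conversion_factor,
)
from .params import (  # packed-parameter slots
    PRE_CM, PRE_GNA, PRE_ENA, PRE_GK, PRE_EK, PRE_GL, PRE_EL, PRE_PHI,
    KP_MAX, KM_MAX, KGHALF, VHALF_KP, KSLOPE, TAU_KP, IMAX_AG, IMAX_WIN, EC50_AG, EC50_WIN,
    NHILL, TAU_G, F_MGL,
    POST_CM, POST_GNA, POST_ENA, POST_GK, POST_EK, POST_GL, POST_EL,
    POST_VT, POST_PHI,
    PMAXL, CAOUT, ZFRT, PZF, VH_INACT, K_INACT, TAU_INACT, TAU_ML_MIN,
    GGABA, EGABA, TAUGABA, ALPHAGABA, V_S, V_THR0, SIGMA_S, REL_FLOOR,
    GAMPA, EAMPA, TAUAMPA,
    EPS_PM, NU0, RHO, VSERCA, KSERCA2, VPMCA, KPMCA2, NULEAK,
    VDAG, KDAG2, KDAGDEG, KSYN, KDEGAG_COX, AGMAX, KAPPA,
)
from .presynaptic import resting_state as _pre_rest, wb_steady_gates
from .postsynaptic import (
    resting_potential as _post_rest_v, traub_steady_gates, _ml_rates,
)
from .cb1 import hill_response_ag, hill_response_win, omega_steady_state
from .signalling import basal_state
from .stimulus import StimulusProgram

__all__ = [
    "CoupledModel", "SimulationResult", "integrate", "initial_state",
    "voltage_clamp_current", "EngineError",
]

_E = 2.718281828459045


class EngineError(RuntimeError):
    """Numerical failure (NaN/Inf) during integration."""


@njit
def _deriv(y, dy, p, vc_pre, vc_post, i_pre, i_post, h_win):
    # ---- presynaptic WB cell
    v = y[IV_PRE]
    h = y[IH_PRE]
    n = y[IN_PRE]
    x = v + 35.0
    am = 0.1 * (10.0 * (1.0 + x / 20.0) if abs(x) < 1e-5
                else x / (1.0 - math.exp(-x / 10.0)))
    bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
    m = am / (am + bm)
    ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-0.1 * (v + 28.0)))
    x = v + 34.0
    an = 0.01 * (10.0 * (1.0 + x / 20.0) if abs(x) < 1e-5
                 else x / (1.0 - math.exp(-x / 10.0)))
    bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
    i_ion = (p[PRE_GNA] * m * m * m * h * (v - p[PRE_ENA])
             + p[PRE_GK] * n ** 4 * (v - p[PRE_EK])
             + p[PRE_GL] * (v - p[PRE_EL]))
    if math.isnan(vc_pre):
        dy[IV_PRE] = (-i_ion + i_pre) / p[PRE_CM]
    else:
        dy[IV_PRE] = 0.0
    phi = p[PRE_PHI]
    dy[IH_PRE] = phi * (ah * (1.0 - h) - bh * h)
    dy[IN_PRE] = phi * (an * (1.0 - n) - bn * n)

    # ---- CB1 receptor / G protein / willing fraction
    ag_eff = p[F_MGL] * y[IAG]
    if ag_eff > 0.0:
        cn = ag_eff ** p[NHILL]
        h_ag = p[IMAX_AG] * cn / (cn + p[EC50_AG] ** p[NHILL])
    else:
        h_ag = 0.0
    h_tot = h_ag + h_win
    if h_tot > 1.0:
        h_tot = 1.0
    dy[IG] = (h_tot - y[IG]) / p[TAU_G]
    # voltage-driven unbinding lags the membrane potential slightly
    vf = y[IVF_PRE]
    dy[IVF_PRE] = (v - vf) / p[TAU_KP]
    kp = p[KP_MAX] / (1.0 + math.exp(-(vf - p[VHALF_KP]) / p[KSLOPE]))
    if p[KGHALF] > 0.0:
        km = p[KM_MAX] * y[IG] / (p[KGHALF] + y[IG])
    else:
        km = p[KM_MAX] * y[IG]
    dy[IOMEGA] = kp * (1.0 - y[IOMEGA]) - km * y[IOMEGA]

    # ---- postsynaptic pyramidal cell
    w = y[IV_POST]
    hq = y[IH_POST]
    nq = y[IN_POST]
    vt = p[POST_VT]
    x = w - vt - 13.0
    am = 0.32 * (4.0 * (1.0 + x / 8.0) if abs(x) < 1e-5
                 else x / (1.0 - math.exp(-x / 4.0)))
    x = -(w - vt - 40.0)
    bm = 0.28 * (5.0 * (1.0 + x / 10.0) if abs(x) < 1e-5
                 else x / (1.0 - math.exp(-x / 5.0)))
    m = am / (am + bm)
    ah = 0.128 * math.exp(-(w - vt - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(w - vt - 40.0) / 5.0))
    x = w - vt - 15.0
    an = 0.032 * (5.0 * (1.0 + x / 10.0) if abs(x) < 1e-5
                  else x / (1.0 - math.exp(-x / 5.0)))
    bn = 0.5 * math.exp(-(w - vt - 10.0) / 40.0)
    i_ion = (p[POST_GNA] * m * m * m * hq * (w - p[POST_ENA])
             + p[POST_GK] * nq ** 4 * (w - p[POST_EK])
             + p[POST_GL] * (w - p[POST_EL]))

    # L-type GHK calcium current (outward positive, uA/cm^2)
    ca = y[ICA_C]
    ml = y[IM_L]
    xg = p[ZFRT] * w * 1e-3
    if abs(xg) < 1e-4:
        g = 1.0 + xg / 2.0 + xg * xg / 12.0 - xg ** 4 / 720.0
        exg = math.exp(-xg)
    else:
        exg = math.exp(-xg)
        g = xg / (1.0 - exg)
    ghk = p[PZF] * g * (ca * 1e-9 - p[CAOUT] * 1e-9 * exg)
    h_l = y[IH_L]
    i_ca = p[PMAXL] * ml * ml * h_l * ghk * 1e6

    s_g = y[IS_GABA]
    s_a = y[IS_AMPA] if y[IS_AMPA] < 1.0 else 1.0
    i_syn = (p[GGABA] * s_g * (w - p[EGABA])
             + p[GAMPA] * s_a * (w - p[EAMPA]))
    if math.isnan(vc_post):
        dy[IV_POST] = (-i_ion - i_ca - i_syn + i_post) / p[POST_CM]
    else:
        dy[IV_POST] = 0.0
    phi = p[POST_PHI]
    dy[IH_POST] = phi * (ah * (1.0 - hq) - bh * hq)
    dy[IN_POST] = phi * (an * (1.0 - nq) - bn * nq)

    # L-gate kinetics
    x = w - 81.5
    a = 15.69 * (10.0 * (1.0 + x / 20.0) if abs(x) < 1e-5
                 else x / (1.0 - math.exp(-x / 10.0)))
    b = 0.29 * math.exp(-w / 10.86)
    tau = 1.0 / (a + b)
    if tau < p[TAU_ML_MIN]:
        tau = p[TAU_ML_MIN]
    dy[IM_L] = (a / (a + b) - ml) / tau
    h_inf = 1.0 / (1.0 + math.exp((w - p[VH_INACT]) / p[K_INACT]))
    dy[IH_L] = (h_inf - h_l) / p[TAU_INACT]

    # ---- calcium / DAG / 2-AG cascade (ms time base)
    j_ch = -p[KAPPA] * i_ca
    er = y[ICA_ER]
    j_leak = p[NULEAK] * (er - ca)
    c2 = ca * ca
    j_serca = p[VSERCA] * c2 / (c2 + p[KSERCA2])
    j_pmca = p[VPMCA] * c2 / (c2 + p[KPMCA2])
    dy[ICA_C] = (j_ch + j_leak - j_serca
                 + p[EPS_PM] * (p[NU0] - j_pmca))
    dy[ICA_ER] = (j_serca - j_leak) / p[RHO]

    dag = y[IDAG]
    ag = y[IAG]
    pox = y[IP_OX]
    prod = p[VDAG] * c2 / (c2 + p[KDAG2])
    cap = 1.0 - (ag + pox) / p[AGMAX]
    if cap < 0.0:
        cap = 0.0
    r1 = p[KSYN] * dag * cap
    r2 = p[KDEGAG_COX] * ag
    dy[IDAG] = prod - p[KDAGDEG] * dag - r1
    dy[IAG] = r1 - r2
    dy[IP_OX] = r2

    # ---- synaptic receptor fractions
    # CB1-sensitive release follows the omega-shifted threshold; a small
    # CB1-insensitive fraction keeps the omega = 1 threshold
    v_thr = p[V_THR0] + p[V_S] * (1.0 - y[IOMEGA])
    f = ((1.0 - p[REL_FLOOR]) / (1.0 + math.exp((v_thr - v) / p[SIGMA_S]))
         + p[REL_FLOOR] / (1.0 + math.exp((p[V_THR0] - v) / p[SIGMA_S])))
    dy[IS_GABA] = p[ALPHAGABA] * f * (1.0 - s_g) - s_g / p[TAUGABA]
    dy[IX_AMPA] = -y[IX_AMPA] / p[TAUAMPA]
    dy[IS_AMPA] = (y[IX_AMPA] - y[IS_AMPA]) / p[TAUAMPA]


@njit
def _run(y, p, dt, n_steps,
         cpre_t, cpre_v, cpost_t, cpost_v,
         ipre_t, ipre_v, ipost_t, ipost_v,
         win_t, hwin_v, ampa_steps,
         rec_stride, rec_t, rec_y,
         ev_t, ev_win, ev_amp):
    icp = icq = iip = iiq = iw = 0
    ia = 0
    iev = 0
    ev_active = -1
    ev_base = 0.0
    rec_i = 0
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    yt = np.empty(NSTATE)
    eps = 1e-9
    for k in range(n_steps + 1):
        t = k * dt
        while icp + 1 < cpre_t.size and t >= cpre_t[icp + 1] - eps:
            icp += 1
        while icq + 1 < cpost_t.size and t >= cpost_t[icq + 1] - eps:
            icq += 1
        while iip + 1 < ipre_t.size and t >= ipre_t[iip + 1] - eps:
            iip += 1
        while iiq + 1 < ipost_t.size and t >= ipost_t[iiq + 1] - eps:
            iiq += 1
        while iw + 1 < win_t.size and t >= win_t[iw + 1] - eps:
            iw += 1
        vcp = cpre_v[icp]
        vcq = cpost_v[icq]
        cur_pre = ipre_v[iip]
        cur_post = ipost_v[iiq]
        hw = hwin_v[iw]
        if not math.isnan(vcp):
            y[IV_PRE] = vcp
        if not math.isnan(vcq):
            y[IV_POST] = vcq
        while ia < ampa_steps.size and ampa_steps[ia] == k:
            y[IX_AMPA] += _E
            ia += 1
        if k % rec_stride == 0:
            if not (math.isfinite(y[IV_PRE]) and math.isfinite(y[IV_POST])
                    and math.isfinite(y[ICA_C])):
                return 1, rec_i
            rec_t[rec_i] = t
            for j in range(NSTATE):
                rec_y[rec_i, j] = y[j]
            rec_i += 1
        if iev < ev_t.size:
            if ev_active < 0 and t >= ev_t[iev] - eps:
                ev_active = iev
                ev_base = y[IS_GABA]
                ev_amp[iev] = 0.0
            if ev_active == iev:
                a = y[IS_GABA] - ev_base
                if a > ev_amp[iev]:
                    ev_amp[iev] = a
                if t >= ev_t[iev] + ev_win - eps:
                    iev += 1
                    ev_active = -1
        if k == n_steps:
            break
        _deriv(y, k1, p, vcp, vcq, cur_pre, cur_post, hw)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _deriv(yt, k2, p, vcp, vcq, cur_pre, cur_post, hw)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _deriv(yt, k3, p, vcp, vcq, cur_pre, cur_post, hw)
        for j in range(NSTATE):
            yt[j] = y[j] + dt * k3[j]
        _deriv(yt, k4, p, vcp, vcq, cur_pre, cur_post, hw)
        for j in range(NSTATE):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if not math.isnan(vcp):
            y[IV_PRE] = vcp
        if not math.isnan(vcq):
            y[IV_POST] = vcq
    return 0, rec_i


@dataclass
class SimulationResult:
    """Time series of all state variables plus evoked-event amplitudes."""

    t: np.ndarray                    # s
    y: np.ndarray                    # (n, NSTATE)
    event_times: np.ndarray          # s, measurement (release) events
    event_amps: np.ndarray           # peak s_gaba per event, baseline-subtracted
    dt_ms: float
    params: ModelParameters
    program: Optional[StimulusProgram] = None
    columns: tuple = STATE_COLUMNS
    schema_version: int = P.SCHEMA_VERSION

    def trace(self, name: str) -> np.ndarray:
        return self.y[:, self.columns.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.columns))
        df.insert(0, "time_s", self.t)
        return df

    def derived(self) -> pd.DataFrame:
        """CB1 activation drive and effective 2-AG alongside the states."""
        df = self.to_dataframe()
        cb1 = self.params.cb1
        ag_eff = cb1.f_mgl * df["ag"].to_numpy()
        df["ag_eff"] = ag_eff
        df["h_ag"] = hill_response_ag(ag_eff, self.params)
        return df


@dataclass
class CoupledModel:
    """Parameter bundle + stimulus program ready for integration."""

    params: ModelParameters = field(default_factory=ModelParameters)
    program: Optional[StimulusProgram] = None

    def run(self, settings: Optional[IntegratorSettings] = None) -> SimulationResult:
        return integrate(self.program, self.params, settings)


def _clamp_value_at(program: StimulusProgram, cell: str, t: float):
    best = None
    for seg in program.clamps:
        if seg.cell == cell and seg.t_start <= t < seg.t_end:
            if best is None or seg.t_start >= best[0]:
                best = (seg.t_start, seg.v_hold)
    return None if best is None else best[1]


def initial_state(params: ModelParameters,
                  program: Optional[StimulusProgram] = None) -> np.ndarray:
    """Resting initial condition consistent with the t = 0 holding clamps.

    Electrical gates start at their steady state for the holding (or
    resting) potential; the calcium/ER pair starts at the basal fixed point
    (leak/SERCA balance for the ER, plasma-membrane balance for the
    cytosol), with DAG/2-AG at their small basal turnover values.
    """
    y = np.zeros(NSTATE)
    vc_pre = _clamp_value_at(program, "pre", 0.0) if program else None
    vc_post = _clamp_value_at(program, "post", 0.0) if program else None
    if vc_pre is None:
        pre = _pre_rest(params)
        y[IV_PRE], y[IH_PRE], y[IN_PRE] = pre
    else:
        y[IV_PRE] = vc_pre
        _, y[IH_PRE], y[IN_PRE] = wb_steady_gates(vc_pre)
    y[IVF_PRE] = y[IV_PRE]
    basal = basal_state(params)
    cb1 = params.cb1
    win0 = 0.0
    if program:
        for seg in program.bath:
            if seg.t_start <= 0.0 < seg.t_end:
                win0 += seg.conc
    h0 = (hill_response_ag(cb1.f_mgl * basal["ag"], params)
          + hill_response_win(win0, params))
    y[IG] = min(h0, 1.0)
    y[IOMEGA] = omega_steady_state(y[IV_PRE], y[IG], params)
    post = params.postsynaptic
    from .postsynaptic import _release_drive, hh_ionic_current, l_type_current
    f0 = _release_drive(float(y[IV_PRE]), float(y[IOMEGA]), post.v_thr0,
                        post.v_s, post.sigma_s, post.release_floor)
    # standing bound fraction at the presynaptic holding potential (omega ~ 1)
    af0 = post.alpha_gaba * f0
    s_standing = af0 / (af0 + 1.0 / post.tau_gaba)
    if vc_post is None:
        from scipy.optimize import brentq as _brentq
        from .postsynaptic import traub_steady_gates as _tsg, _ml_rates as _mlr

        def _net(v):
            _, hh, nn = _tsg(v, post.v_t)
            a, b = _mlr(v)
            h_l = 1.0 / (1.0 + math.exp((v - post.v_half_inact) / post.k_inact))
            i_ca, _, _ = l_type_current(v, a / (a + b), h_l, 0.02, params)
            i_syn = post.g_gaba * s_standing * (v - post.e_gaba)
            return (hh_ionic_current(v, hh, nn, post.v_t, post.g_na, post.e_na,
                                     post.g_k, post.e_k, post.g_l, post.e_l)
                    + i_ca + i_syn)

        v_post = _brentq(_net, -95.0, -55.0, xtol=1e-12)
    else:
        v_post = vc_post
    y[IV_POST] = v_post
    _, y[IH_POST], y[IN_POST] = traub_steady_gates(v_post, params.postsynaptic.v_t)
    a, b = _ml_rates(float(v_post))
    y[IM_L] = a / (a + b)
    y[IH_L] = 1.0 / (1.0 + math.exp(
        (v_post - params.postsynaptic.v_half_inact) / params.postsynaptic.k_inact))
    y[ICA_C] = basal["ca_c"]
    y[ICA_ER] = basal["ca_er"]
    y[IDAG] = basal["dag"]
    y[IAG] = basal["ag"]
    y[IP_OX] = 0.0
    y[IS_GABA] = s_standing
    return y


def _unit_audit(params: ModelParameters, packed: np.ndarray) -> None:
    sig = params.signalling
    post = params.postsynaptic
    kappa = flux_conversion_factor(sig.radius, sig.beta_buf, post.z,
                                   post.faraday) * 1e-3
    if not math.isclose(kappa, packed[KAPPA], rel_tol=1e-12):
        raise EngineError("current-to-flux conversion factor failed unit audit")


def integrate(program: StimulusProgram,
              params: Optional[ModelParameters] = None,
              settings: Optional[IntegratorSettings] = None,
              y0: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate the coupled model over a stimulus program.

    ``settings.method = 'reference'`` halves the step for oracle runs.
    Deterministic: no randomness is consumed anywhere.
    """
    params = (params or ModelParameters()).validate()
    settings = settings or params.integrator
    settings.validate()
    dt = settings.dt / 2.0 if settings.method == "reference" else settings.dt
    packed = pack_parameters(params)
    _unit_audit(params, packed)
    comp = program.compile(dt)
    n_steps = comp["n_steps"]
    rec_stride = max(1, int(round(settings.record_dt / dt)))
    n_rec = n_steps // rec_stride + 1
    rec_t = np.empty(n_rec)
    rec_y = np.empty((n_rec, NSTATE))
    ev_amp = np.zeros(comp["ev_t"].size)
    hwin_v = np.array([hill_response_win(c, params) for c in comp["win_v"]])
    y = (initial_state(params, program) if y0 is None else np.array(y0, dtype=float))
    status, n_got = _run(
        y, packed, dt, n_steps,
        comp["cpre_t"], comp["cpre_v"], comp["cpost_t"], comp["cpost_v"],
        comp["ipre_t"], comp["ipre_v"], comp["ipost_t"], comp["ipost_v"],
        comp["win_t"], hwin_v, comp["ampa_steps"],
        rec_stride, rec_t, rec_y,
        comp["ev_t"], comp["ev_win"], ev_amp)
    if status != 0:
        err = EngineError(
            f"non-finite state at t = {n_got * rec_stride * dt:.3f} ms; "
            f"last valid sample index {n_got - 1}")
        err.last_valid = SimulationResult(  # type: ignore[attr-defined]
            rec_t[:n_got] * 1e-3, rec_y[:n_got].copy(),
            comp["ev_t"] * 1e-3, ev_amp, dt, params, program)
        raise err
    return SimulationResult(rec_t[:n_got] * 1e-3, rec_y[:n_got], comp["ev_t"] * 1e-3,
                            ev_amp, dt, params, program)


def voltage_clamp_current(state: np.ndarray, params: ModelParameters,
                          i_app: float = 0.0) -> float:
    """Command current (uA/cm^2) holding the postsynaptic cell at its
    present potential: exactly balances membrane plus synaptic currents so
    that dV/dt = 0."""
    from .postsynaptic import hh_ionic_current, l_type_current
    post = params.postsynaptic
    w = state[IV_POST]
    i_ion = hh_ionic_current(w, state[IH_POST], state[IN_POST], post.v_t,
                             post.g_na, post.e_na, post.g_k, post.e_k,
                             post.g_l, post.e_l)
    i_ca, _, _ = l_type_current(w, state[IM_L], state[IH_L], state[ICA_C], params)
    s_a = min(state[IS_AMPA], 1.0)
    i_syn = (post.g_gaba * state[IS_GABA] * (w - post.e_gaba)
             + post.g_ampa * s_a * (w - post.e_ampa))
    return i_ion + i_ca + i_syn - i_app
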