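"""Postsynaptic pyramidal cell: HH spiking currents, GHK L-type calcium
channel, and GABA_A/AMPA synapses.

Spiking currents use the Traub-derived kinetics of hippocampal pyramidal
cells (Huguenard-style, with a threshold shift v_t): sodium activation is
instantaneous (m_inf^3 h), the delayed rectifier is n^4.  The L-type
voltage-gated calcium channel carries a Goldman-Hodgkin-Katz (constant
field) flux with fast activation gate m_L^2 and a slow voltage-dependent
inactivation gate h_L; its permeability P_max_L is small enough
that the current is negligible at rest but substantial during depolarisation
to 0 mV, where the GHK nonlinearity matters.

GABA release omits explicit transmitter kinetics: the fraction of bound
GABA_A receptors s is driven by a sigmoid of the *presynaptic* voltage whose
half-maximal voltage rises as presynaptic calcium channels become reluctant
(omega falls), so CB1 activation directly scales the evoked IPSP.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from ._numba import njit
from .params import ModelParameters, phi_temperature

__all__ = [
    "traub_rates", "ghk_driving_force", "l_type_current",
    "gaba_synapse_rhs", "ampa_alpha_train", "resting_potential",
]


@njit
def _vtrap(x: float, y: float) -> float:
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


# -- Traub/Huguenard spiking kinetics (ms^-1, mV) ---------------------------

@njit
def _tr_alpha_m(v: float, vt: float) -> float:
    return 0.32 * _vtrap(v - vt - 13.0, 4.0)


@njit
def _tr_beta_m(v: float, vt: float) -> float:
    return 0.28 * _vtrap(-(v - vt - 40.0), 5.0)


@njit
def _tr_alpha_h(v: float, vt: float) -> float:
    return 0.128 * math.exp(-(v - vt - 17.0) / 18.0)


@njit
def _tr_beta_h(v: float, vt: float) -> float:
    return 4.0 / (1.0 + math.exp(-(v - vt - 40.0) / 5.0))


@njit
def _tr_alpha_n(v: float, vt: float) -> float:
    return 0.032 * _vtrap(v - vt - 15.0, 5.0)


@njit
def _tr_beta_n(v: float, vt: float) -> float:
    return 0.5 * math.exp(-(v - vt - 10.0) / 40.0)


def traub_rates(v: float, v_t: float = -55.0) -> dict:
    """Gating rates for the pyramidal-cell Na/K currents at voltage ``v``."""
    if not np.isfinite(v):
        raise ValueError("membrane potential must be finite")
    am, bm = _tr_alpha_m(v, v_t), _tr_beta_m(v, v_t)
    return {
        "m_inf": am / (am + bm),
        "alpha_h": _tr_alpha_h(v, v_t), "beta_h": _tr_beta_h(v, v_t),
        "alpha_n": _tr_alpha_n(v, v_t), "beta_n": _tr_beta_n(v, v_t),
    }


def traub_steady_gates(v: float, v_t: float = -55.0) -> tuple:
    r = traub_rates(v, v_t)
    h_inf = r["alpha_h"] / (r["alpha_h"] + r["beta_h"])
    n_inf = r["alpha_n"] / (r["alpha_n"] + r["beta_n"])
    return r["m_inf"], h_inf, n_inf


@njit
def hh_ionic_current(v: float, h: float, n: float, vt: float, g_na: float,
                     e_na: float, g_k: float, e_k: float, g_l: float,
                     e_l: float) -> float:
    am, bm = _tr_alpha_m(v, vt), _tr_beta_m(v, vt)
    m = am / (am + bm)
    return (g_na * m * m * m * h * (v - e_na)
            + g_k * n ** 4 * (v - e_k) + g_l * (v - e_l))


# -- GHK L-type calcium channel ---------------------------------------------

@njit
def _ghk_factor(v_mv: float, ca_in: float, ca_out: float, zfrt: float,
                pzf: float) -> float:
    """GHK flux factor in A/cm^2 per (cm/s) of permeability.

    Voltages in mV; concentrations in uM (converted to mol/cm^3 inside).
    ``zfrt`` is zF/RT per volt, ``pzf`` is zF.  Continuous through V = 0 via
    a series expansion of x/(1 - e^-x).
    """
    ci = ca_in * 1e-9   # uM -> mol/cm^3
    co = ca_out * 1e-9
    x = zfrt * v_mv * 1e-3
    if abs(x) < 1e-4:
        g = 1.0 + x / 2.0 + x * x / 12.0 - x ** 4 / 720.0
        ex = math.exp(-x)
    else:
        ex = math.exp(-x)
        g = x / (1.0 - ex)
    return pzf * g * (ci - co * ex)


def ghk_driving_force(v: float, ca_in: float, ca_out: float,
                      temperature_k: float, z: float = 2.0) -> float:
    """GHK driving-force factor (A/cm^2 per cm/s permeability).

    Negative (inward) for physiological gradients at sub-zero voltages; the
    removable singularity at V = 0 is handled by series expansion.
    """
    if ca_in <= 0 or ca_out <= 0:
        raise ValueError("calcium concentrations must be > 0")
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0 K")
    from .params import FARADAY, GAS_CONSTANT
    zfrt = z * FARADAY / (GAS_CONSTANT * temperature_k)
    return _ghk_factor(float(v), ca_in, ca_out, zfrt, z * FARADAY)


@njit
def _ml_rates(v: float):
    """L-type activation-gate rates (ms^-1), hippocampal GHK channel form."""
    # 15.69*(81.5-v)/(exp((81.5-v)/10)-1), singularity-safe
    a = 15.69 * _vtrap(v - 81.5, 10.0)
    b = 0.29 * math.exp(-v / 10.86)
    return a, b


def l_type_current(v: float, m_l: float, h_l: float, ca_in: float,
                   params: ModelParameters | None = None) -> tuple:
    """L-type calcium current (uA/cm^2, outward positive) and gate rates.

    I = P_max m_L^2 h_L ghk(V).  The activation gate m_L follows fast
    voltage-dependent kinetics; h_L is a slow voltage-dependent
    inactivation gate (time constant tau_inact) that limits influx during
    sustained depolarisation while leaving brief spikes unaffected.
    Returns (I_Ca, dm_L/dt, dh_L/dt).
    """
    post = (params or ModelParameters()).postsynaptic
    ghk = ghk_driving_force(v, ca_in, post.ca_out, post.temperature_k, post.z)
    i_ca = post.p_max_l * m_l * m_l * h_l * ghk * 1e6  # A -> uA
    a, b = _ml_rates(float(v))
    tau = max(1.0 / (a + b), post.tau_ml_min)
    dm = (a / (a + b) - m_l) / tau
    h_inf = 1.0 / (1.0 + math.exp((v - post.v_half_inact) / post.k_inact))
    dh = (h_inf - h_l) / post.tau_inact
    return i_ca, dm, dh


# -- synapses ---------------------------------------------------------------

@njit
def _release_drive(v_pre: float, omega: float, v_thr0: float, v_s: float,
                   sigma_s: float, floor: float) -> float:
    """Sigmoidal GABA release drive F(V_pre; omega) in [0, 1].

    The CB1-sensitive component has half-maximal voltage
    v_thr0 + v_s (1 - omega); a small CB1-insensitive fraction ``floor``
    keeps the unshifted threshold (reluctant channels still support a
    little release on strong depolarisation).
    """
    v_thr = v_thr0 + v_s * (1.0 - omega)
    return ((1.0 - floor) / (1.0 + math.exp((v_thr - v_pre) / sigma_s))
            + floor / (1.0 + math.exp((v_thr0 - v_pre) / sigma_s)))


def gaba_synapse_rhs(s_gaba: float, v_pre: float, omega: float,
                     params: ModelParameters | None = None) -> tuple:
    """ds/dt (ms^-1) for bound GABA_A receptors and the conductance.

    ds/dt = alpha F(V_pre; omega) (1 - s) - s / tau_gaba.
    Returns (ds_dt, g) with g = g_gaba * s (mS/cm^2).
    """
    post = (params or ModelParameters()).postsynaptic
    f = _release_drive(float(v_pre), float(omega), post.v_thr0, post.v_s,
                       post.sigma_s, post.release_floor)
    ds = post.alpha_gaba * f * (1.0 - s_gaba) - s_gaba / post.tau_gaba
    return ds, post.g_gaba * s_gaba


def ampa_alpha_train(event_times, t, params: ModelParameters | None = None):
    """Closed-form AMPA bound fraction: sum of alpha kernels, clipped to 1.

    Each event contributes (dt/tau) e^(1 - dt/tau), peaking at exactly one
    tau after onset with unit amplitude.  ``event_times`` must be sorted.
    """
    post = (params or ModelParameters()).postsynaptic
    ev = np.asarray(event_times, dtype=float)
    if ev.size > 1 and np.any(np.diff(ev) < 0):
        raise ValueError("event times must be sorted")
    t = np.asarray(t, dtype=float)
    s = np.zeros_like(t, dtype=float)
    tau = post.tau_ampa
    for t0 in ev:
        dt = t - t0
        mask = dt >= 0
        s[mask] += (dt[mask] / tau) * np.exp(1.0 - dt[mask] / tau)
    return np.clip(s, 0.0, 1.0)


def resting_potential(params: ModelParameters | None = None) -> float:
    """Resting potential of the isolated pyramidal cell (no synapses)."""
    post = (params or ModelParameters()).postsynaptic

    def f(v):
        _, h, n = traub_steady_gates(v, post.v_t)
        return hh_ionic_current(v, h, n, post.v_t, post.g_na, post.e_na,
                                post.g_k, post.e_k, post.g_l, post.e_l)

    return brentq(f, -95.0, -55.0, xtol=1e-10)


def pyramidal_rhs(state, params: ModelParameters, i_app: float = 0.0,
                  i_syn: float = 0.0, ca_in: float = 0.02):
    """Derivatives of (V, h, n, m_L, h_L) for the isolated pyramidal cell.

    Membrane currents are outward-positive:
    C dV/dt = -I_ion - I_L - I_syn + I_app.
    """
    v, h, n, m_l, h_l = (float(x) for x in state[:5])
    if not all(np.isfinite([v, h, n, m_l, h_l])):
        raise ValueError("non-finite postsynaptic state")
    post = params.postsynaptic
    phi = phi_temperature(post.t_exp, post.t_sim, post.q10)
    i_ion = hh_ionic_current(v, h, n, post.v_t, post.g_na, post.e_na,
                             post.g_k, post.e_k, post.g_l, post.e_l)
    i_ca, dm, dh_l = l_type_current(v, m_l, h_l, ca_in, params)
    dv = (-i_ion - i_ca - i_syn + i_app) / post.c_m
    dh = phi * (_tr_alpha_h(v, post.v_t) * (1 - h) - _tr_beta_h(v, post.v_t) * h)
    dn = phi * (_tr_alpha_n(v, post.v_t) * (1 - n) - _tr_beta_n(v, post.v_t) * n)
    return np.array([dv, dh, dn, dm, dh_l])
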