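"""Wang-Buzsaki fast-spiking interneuron: rate functions and dynamics.

The presynaptic inhibitory cell is the standard WB single-compartment model:
an instantaneously activating sodium current g_Na m_inf^3 h (V - E_Na), a
delayed rectifier g_K n^4 (V - E_K) and a leak.  The gating rates below are
the published WB forms (in ms^-1, voltages in mV); a Q10 temperature factor
phi multiplies all rates.  The WB parameterisation fires repetitive spikes at
high frequency with a brief afterhyperpolarisation, matching fast-spiking
hippocampal interneurons.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from ._numba import njit
from .params import (
    IV_PRE, IH_PRE, IN_PRE, ModelParameters, phi_temperature,  # noqa: F401
)

__all__ = [
    "wb_rates", "wb_steady_gates", "presynaptic_rhs", "resting_potential",
    "phi_temperature",
]


@njit
def _vtrap(x: float, y: float) -> float:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


@njit
def _wb_alpha_m(v: float) -> float:
    return 0.1 * _vtrap(v + 35.0, 10.0)


@njit
def _wb_beta_m(v: float) -> float:
    return 4.0 * math.exp(-(v + 60.0) / 18.0)


@njit
def _wb_alpha_h(v: float) -> float:
    return 0.07 * math.exp(-(v + 58.0) / 20.0)


@njit
def _wb_beta_h(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-0.1 * (v + 28.0)))


@njit
def _wb_alpha_n(v: float) -> float:
    return 0.01 * _vtrap(v + 34.0, 10.0)


@njit
def _wb_beta_n(v: float) -> float:
    return 0.125 * math.exp(-(v + 44.0) / 80.0)


def wb_rates(v: float) -> dict:
    """Gating rates at voltage ``v`` (mV).

    Returns a dict with (alpha, beta) for h and n and the instantaneous
    sodium activation ``m_inf`` = alpha_m/(alpha_m + beta_m).
    """
    if not np.isfinite(v):
        raise ValueError("membrane potential must be finite")
    am, bm = _wb_alpha_m(v), _wb_beta_m(v)
    return {
        "m_inf": am / (am + bm),
        "alpha_h": _wb_alpha_h(v), "beta_h": _wb_beta_h(v),
        "alpha_n": _wb_alpha_n(v), "beta_n": _wb_beta_n(v),
    }


def wb_steady_gates(v: float) -> tuple:
    """Steady-state (m_inf, h_inf, n_inf) at voltage ``v``."""
    r = wb_rates(v)
    h_inf = r["alpha_h"] / (r["alpha_h"] + r["beta_h"])
    n_inf = r["alpha_n"] / (r["alpha_n"] + r["beta_n"])
    return r["m_inf"], h_inf, n_inf


@njit
def wb_ionic_current(v: float, h: float, n: float, g_na: float, e_na: float,
                     g_k: float, e_k: float, g_l: float, e_l: float) -> float:
    am, bm = _wb_alpha_m(v), _wb_beta_m(v)
    m = am / (am + bm)
    i_na = g_na * m * m * m * h * (v - e_na)
    i_k = g_k * n ** 4 * (v - e_k)
    i_l = g_l * (v - e_l)
    return i_na + i_k + i_l


@njit
def wb_gate_derivatives(v: float, h: float, n: float, phi: float):
    dh = phi * (_wb_alpha_h(v) * (1.0 - h) - _wb_beta_h(v) * h)
    dn = phi * (_wb_alpha_n(v) * (1.0 - n) - _wb_beta_n(v) * n)
    return dh, dn


def presynaptic_rhs(state, params: ModelParameters, i_app: float = 0.0):
    """Time derivative of (V, h, n) for the isolated WB cell.

    ``state`` is a length-3 sequence (V in mV, gates dimensionless); current
    in uA/cm^2.  Raises on non-finite state.
    """
    v, h, n = float(state[0]), float(state[1]), float(state[2])
    if not (np.isfinite(v) and np.isfinite(h) and np.isfinite(n)):
        raise ValueError("non-finite presynaptic state")
    pre = params.presynaptic
    phi = phi_temperature(pre.t_exp, pre.t_sim, pre.q10)
    i_ion = wb_ionic_current(v, h, n, pre.g_na, pre.e_na, pre.g_k, pre.e_k,
                             pre.g_l, pre.e_l)
    dv = (-i_ion + i_app) / pre.c_m
    dh, dn = wb_gate_derivatives(v, h, n, phi)
    return np.array([dv, dh, dn])


def resting_potential(params: ModelParameters) -> float:
    """Resting membrane potential (gates at steady state, I_app = 0)."""
    pre = params.presynaptic

    def f(v):
        _, h, n = wb_steady_gates(v)
        return wb_ionic_current(v, h, n, pre.g_na, pre.e_na, pre.g_k,
                                pre.e_k, pre.g_l, pre.e_l)

    # upper bound stays below the unstable middle fixed point (~ -59 mV)
    return brentq(f, -90.0, -60.0, xtol=1e-10)


def resting_state(params: ModelParameters) -> np.ndarray:
    v = resting_potential(params)
    _, h, n = wb_steady_gates(v)
    return np.array([v, h, n])
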