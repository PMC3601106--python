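"""CB1 receptor activation and willing/reluctant gating of presynaptic
N-type calcium channels.

The receptor cascade is deliberately minimal.  Agonist binding (endogenous
2-AG after MGL attenuation, plus any bath WIN55,212) drives a single pooled
G-protein activation variable G with first-order kinetics,

    dG/dt = (H_AG(AG_eff) + H_WIN(WIN) - G) / tau_G,

where H are Hill concentration-response curves for N-channel inhibition.
Activated G proteins shift channels from a willing to a reluctant state;
depolarisation reverses the shift:

    d(omega)/dt = k_plus(V) (1 - omega) - k_minus_max G omega,

with k_plus a rising sigmoid of the presynaptic voltage.  omega multiplies
nothing directly here - it sets the half-maximal voltage of GABA release
(see :mod:`ecbdsi.postsynaptic`).
"""

from __future__ import annotations

import math

import numpy as np

from ._numba import njit
from .params import ModelParameters

__all__ = [
    "hill_response_ag", "hill_response_win", "effective_ag",
    "g_protein_rhs", "k_plus", "willing_fraction_rhs",
]


@njit
def _hill(c: float, imax: float, ec50: float, n: float) -> float:
    if c <= 0.0:
        return 0.0
    cn = c ** n
    return imax * cn / (cn + ec50 ** n)


def _check_conc(c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("agonist concentration must be >= 0")
    return c


def hill_response_ag(c, params: ModelParameters | None = None):
    """N-channel inhibition level for 2-AG concentration ``c`` (uM)."""
    cb1 = (params or ModelParameters()).cb1
    c = _check_conc(c)
    out = np.vectorize(_hill)(c, cb1.i_max_ag, cb1.ec50_ag, cb1.n_hill)
    return float(out) if out.ndim == 0 else out


def hill_response_win(c, params: ModelParameters | None = None):
    """N-channel inhibition level for WIN55,212 concentration ``c`` (uM)."""
    cb1 = (params or ModelParameters()).cb1
    c = _check_conc(c)
    out = np.vectorize(_hill)(c, cb1.i_max_win, cb1.ec50_win, cb1.n_hill)
    return float(out) if out.ndim == 0 else out


def effective_ag(ag_post: float, f_mgl: float) -> float:
    """2-AG surviving presynaptic MGL degradation: f_mgl * ag_post."""
    if ag_post < 0:
        raise ValueError("ag_post must be >= 0")
    if not (0.0 <= f_mgl <= 1.0):
        raise ValueError("f_mgl must be in [0, 1]")
    return f_mgl * ag_post


def g_protein_rhs(g: float, h_total: float, tau_g: float = 1000.0) -> float:
    """dG/dt (ms^-1): relaxation of bound G towards the receptor drive."""
    return (h_total - g) / tau_g


@njit
def _k_plus(v: float, k_max: float, v_half: float, slope: float) -> float:
    return k_max / (1.0 + math.exp(-(v - v_half) / slope))


def k_plus(v: float, params: ModelParameters | None = None) -> float:
    """Voltage-dependent reluctant-to-willing rate (ms^-1)."""
    cb1 = (params or ModelParameters()).cb1
    return _k_plus(float(v), cb1.k_plus_max, cb1.v_half_kplus, cb1.k_slope)


def k_minus(g: float, params: ModelParameters | None = None) -> float:
    """G-protein-dependent willing-to-reluctant rate (ms^-1).

    Linear in G by default; saturable (Michaelis form with constant
    k_g_half) when configured.
    """
    cb1 = (params or ModelParameters()).cb1
    if cb1.k_g_half > 0.0:
        return cb1.k_minus_max * g / (cb1.k_g_half + g)
    return cb1.k_minus_max * g


def willing_fraction_rhs(omega: float, v_pre: float, g: float,
                         params: ModelParameters | None = None) -> float:
    """d(omega)/dt (ms^-1) for the willing-channel fraction."""
    cb1 = (params or ModelParameters()).cb1
    kp = _k_plus(float(v_pre), cb1.k_plus_max, cb1.v_half_kplus, cb1.k_slope)
    km = k_minus(g, params)
    return kp * (1.0 - omega) - km * omega


def omega_steady_state(v_pre: float, g: float,
                       params: ModelParameters | None = None) -> float:
    """Fixed point k_plus/(k_plus + k_minus) of the omega kinetics."""
    cb1 = (params or ModelParameters()).cb1
    kp = _k_plus(float(v_pre), cb1.k_plus_max, cb1.v_half_kplus, cb1.k_slope)
    km = k_minus(g, params)
    if kp + km == 0.0:
        return 1.0
    return kp / (kp + km)
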