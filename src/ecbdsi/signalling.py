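"""Postsynaptic calcium, DAG and 2-AG signalling.

A well-mixed two-pool calcium model (cytosol + ER) drives a
calcium-dependent, PLC-beta-independent DAG synthesis pathway, and DAG is
metabolised by DGL-alpha to the endocannabinoid 2-AG, which COX-2 oxidises
to an inert product P:

    dCa_c/dt  = J_ch + nu_leak (Ca_ER - Ca_c) - J_serca + eps (nu0 - J_pmca)
    dCa_ER/dt = (J_serca - nu_leak (Ca_ER - Ca_c)) / rho
    dDAG/dt   = V_dag Hill2(Ca_c; K_dag) - k_dag_deg DAG - R1
    dAG/dt    = R1 - R2,    dP/dt = R2
    R1 = k_syn DAG (1 - (AG + P)/AG_max),   R2 = k_deg_ag COX2 AG

Pumps are Hill functions with coefficient 2.  The (AG + P)/AG_max factor
caps the total mobilisable 2-AG pool at AG_max; d(AG + P)/dt = R1 exactly,
which the engine verifies along trajectories (closed AG <-> P bookkeeping).
The channel flux J_ch converts the L-type current to uM/s through the
surface-to-volume factor of a 10 um spherical soma scaled by the fast-buffer
fraction beta_buf.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from ._numba import njit
from .params import ModelParameters, ParameterError, flux_conversion_factor

__all__ = [
    "pump_flux", "calcium_rhs", "current_to_flux", "dag_rhs", "ag_rhs",
    "basal_state",
]


@njit
def _hill2(c: float, vmax: float, k2: float) -> float:
    c2 = c * c
    return vmax * c2 / (c2 + k2)


def pump_flux(c: float, vmax: float, k: float) -> float:
    """Hill-2 pump rate Vmax c^2/(c^2 + K^2) (uM/s for uM inputs)."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return _hill2(float(c), vmax, k * k)


def current_to_flux(i_ca: float, radius_um: float, beta_buf: float,
                    z: float = 2.0) -> float:
    """Convert a membrane calcium current (uA/cm^2, outward positive) to a
    cytosolic flux (uM/s); inward current gives positive influx."""
    kappa = flux_conversion_factor(radius_um, beta_buf, z)
    return -kappa * i_ca


def calcium_rhs(ca_c: float, ca_er: float, j_channel: float,
                params: ModelParameters | None = None) -> tuple:
    """(dCa_c/dt, dCa_ER/dt) in uM/s given the channel influx (uM/s)."""
    sig = (params or ModelParameters()).signalling
    j_leak = sig.nu_leak * (ca_er - ca_c)
    j_serca = _hill2(ca_c, sig.v_serca, sig.k_serca ** 2)
    j_pmca = _hill2(ca_c, sig.v_pmca, sig.k_pmca ** 2)
    dca = j_channel + j_leak - j_serca + sig.eps_pm * (sig.nu0_effective() - j_pmca)
    der = (j_serca - j_leak) / sig.rho
    return dca, der


def dag_rhs(dag: float, ca_c: float, ag: float = 0.0, p_ox: float = 0.0,
            params: ModelParameters | None = None) -> float:
    """dDAG/dt (uM/s): Hill-2 calcium-evoked production minus degradation
    and DGL consumption."""
    sig = (params or ModelParameters()).signalling
    prod = _hill2(ca_c, sig.v_dag, sig.k_dag ** 2)
    r1 = sig.k_syn * dag * max(0.0, 1.0 - (ag + p_ox) / sig.ag_max)
    return prod - sig.k_dag_deg * dag - r1


def ag_rhs(ag: float, p_ox: float, dag: float,
           params: ModelParameters | None = None) -> tuple:
    """(dAG/dt, dP/dt) in uM/s; d(AG + P)/dt equals the synthesis inflow."""
    sig = (params or ModelParameters()).signalling
    if ag < 0 or p_ox < 0:
        raise ValueError("concentrations must be >= 0")
    r1 = sig.k_syn * dag * max(0.0, 1.0 - (ag + p_ox) / sig.ag_max)
    r2 = sig.k_deg_ag * sig.cox2 * ag
    return r1 - r2, r2


def basal_state(params: ModelParameters, j_channel: float = 0.0) -> dict:
    """Basal fixed point of the signalling subsystem.

    Solves the cytosolic balance (with optional constant channel flux) for
    Ca_c, sets Ca_ER at the leak/SERCA balance, and DAG/AG at their
    production/degradation balance.  With the default nu0 this returns
    Ca_c = 0.02 uM exactly.
    """
    sig = params.signalling
    if sig.nu_leak <= 0:
        raise ParameterError("basal state needs nu_leak > 0")

    def net(ca):
        # at ER balance j_serca == j_leak, so cytosolic balance reduces to
        # plasma-membrane terms plus the channel flux
        j_pmca = _hill2(ca, sig.v_pmca, sig.k_pmca ** 2)
        return j_channel + sig.eps_pm * (sig.nu0_effective() - j_pmca)

    ca = brentq(net, 1e-6, 100.0, xtol=1e-12)
    ca_er = ca + _hill2(ca, sig.v_serca, sig.k_serca ** 2) / sig.nu_leak
    prod = _hill2(ca, sig.v_dag, sig.k_dag ** 2)
    # small-signal balance ignoring the pool-cap factor (AG + P << AG_max)
    dag = prod / (sig.k_dag_deg + sig.k_syn)
    elim = sig.k_deg_ag * sig.cox2
    ag = sig.k_syn * dag / elim if elim > 0 else 0.0
    return {"ca_c": ca, "ca_er": ca_er, "dag": dag, "ag": ag}
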