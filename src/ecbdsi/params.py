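"""Parameter containers, validation, serialisation and kernel packing.

The model couples a fast-spiking Wang-Buzsaki (WB) interneuron to a single
compartment pyramidal cell through a plastic GABA_A synapse whose release is
gated by CB1-receptor/G-protein inhibition of presynaptic N-type calcium
channels.  Parameters are grouped the way the biology is: presynaptic
electrical cell, CB1 receptor cascade, postsynaptic electrical cell (HH +
L-type VGCC + synapses), and the postsynaptic calcium/DAG/2-AG signalling
cascade.

User-facing units follow the conventions of the field: membrane quantities in
mV, ms, uF/cm^2, mS/cm^2, uA/cm^2; signalling concentrations in uM and rates
in s^-1 (converted to a single ms time base when packed for the integrator).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "PresynapticParameters",
    "CB1Parameters",
    "PostsynapticParameters",
    "SignallingParameters",
    "IntegratorSettings",
    "ModelParameters",
    "ParameterError",
    "pack_parameters",
]

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# state-vector layout (integrated variables)
# ---------------------------------------------------------------------------
IV_PRE, IH_PRE, IN_PRE, IOMEGA, IG, IVF_PRE = 0, 1, 2, 3, 4, 5
IV_POST, IH_POST, IN_POST, IM_L, IH_L = 6, 7, 8, 9, 10
ICA_C, ICA_ER, IDAG, IAG, IP_OX = 11, 12, 13, 14, 15
IS_GABA, IS_AMPA, IX_AMPA = 16, 17, 18
NSTATE = 19

STATE_COLUMNS = (
    "v_pre", "h_pre", "n_pre", "omega", "g_cb1", "vf_pre",
    "v_post", "h_post", "n_post", "m_l", "h_l",
    "ca_c", "ca_er", "dag", "ag", "p_ox",
    "s_gaba", "s_ampa", "x_ampa",
)

SCHEMA_VERSION = 1


@dataclass
class PresynapticParameters:
    """Wang-Buzsaki fast-spiking interneuron (single compartment).

    Kinetic constants are the published WB values; the temperature factor
    phi = q10**((t_sim - t_exp)/10) multiplies all gating rates and equals
    the WB phi = 5 at the default (t_exp=15 C, t_sim=25 C, q10=5).
    """

    c_m: float = 1.0          # uF/cm^2
    g_na: float = 35.0        # mS/cm^2
    e_na: float = 55.0        # mV
    g_k: float = 9.0
    e_k: float = -90.0
    g_l: float = 0.1
    e_l: float = -65.0
    q10: float = 5.0
    t_exp: float = 15.0       # C
    t_sim: float = 25.0       # C

    def validate(self) -> None:
        for name in ("c_m", "g_na", "g_k", "g_l"):
            if getattr(self, name) < 0:
                raise ParameterError(f"presynaptic.{name} must be >= 0")
        if self.q10 <= 0:
            raise ParameterError("presynaptic.q10 must be > 0")
        for name in ("t_exp", "t_sim"):
            t = getattr(self, name)
            if not (0.0 <= t <= 45.0):
                raise ParameterError(f"presynaptic.{name} outside 0-45 C")


@dataclass
class CB1Parameters:
    """CB1 receptor, G-protein pool and willing/reluctant N-channel gating.

    The willing fraction omega relaxes as
    d(omega)/dt = k_plus(V)(1 - omega) - k_minus(G) omega with a sigmoidal
    voltage-dependent recovery rate k_plus and k_minus = k_minus_max * G.
    Receptor drive is the sum of two Hill concentration-response curves
    (2-AG and WIN55,212) with shared Hill coefficient 1.2.
    """

    k_plus_max: float = 0.3      # ms^-1, reluctant -> willing ceiling
    k_minus_max: float = 0.0006  # ms^-1, willing -> reluctant scale
    k_g_half: float = 0.0        # uM-free saturation constant of k_minus(G);
    #                              0 = linear k_minus = k_minus_max * G
    v_half_kplus: float = 14.0   # mV, half-maximum of the k_plus sigmoid
    k_slope: float = 11.15       # mV, sigmoid slope
    tau_kplus: float = 0.5       # ms, lag of voltage-driven G-beta-gamma
    #                              unbinding (k_plus follows a low-pass
    #                              filtered presynaptic voltage)
    i_max_ag: float = 0.5
    i_max_win: float = 0.48
    ec50_ag: float = 0.48        # uM
    ec50_win: float = 0.002      # uM
    n_hill: float = 1.2
    tau_g: float = 1000.0        # ms, CB1 unbinding time constant
    f_mgl: float = 1.0           # fraction of 2-AG surviving MGL degradation
    win_conc: float = 0.0        # uM bath agonist (overridden by protocols)

    def validate(self) -> None:
        for name in ("k_plus_max", "k_minus_max", "ec50_ag", "ec50_win",
                     "tau_g", "n_hill", "k_slope", "tau_kplus"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"cb1.{name} must be > 0")
        for name in ("i_max_ag", "i_max_win"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"cb1.{name} must be in (0, 1]")
        if not (0.0 <= self.f_mgl <= 1.0):
            raise ParameterError("cb1.f_mgl must be in [0, 1]")
        if self.win_conc < 0:
            raise ParameterError("cb1.win_conc must be >= 0")
        if self.k_g_half < 0:
            raise ParameterError("cb1.k_g_half must be >= 0")


@dataclass
class PostsynapticParameters:
    """Pyramidal cell: Traub/Huguenard HH spiking currents, GHK L-type
    calcium channel and GABA_A/AMPA synaptic inputs.

    The GABA_A activation is a sigmoid of the presynaptic voltage whose
    half-maximal voltage v_thr = v_thr0 + v_s*(1 - omega) shifts with the
    willing-channel fraction: omega = 1 gives a full-sized response to a
    presynaptic spike, omega -> 0 moves the threshold far above spike peak.
    """

    c_m: float = 1.0
    g_na: float = 50.0
    e_na: float = 50.0
    g_k: float = 5.0
    e_k: float = -90.0
    g_l: float = 0.1
    e_l: float = -70.0
    v_t: float = -55.0          # mV, Traub kinetics threshold shift
    q10: float = 3.0
    t_exp: float = 25.0
    t_sim: float = 25.0
    # L-type VGCC (GHK formulation)
    p_max_l: float = 0.000275   # cm/s maximum permeability
    ca_out: float = 2000.0      # uM extracellular calcium
    z: float = 2.0
    faraday: float = FARADAY
    gas_constant: float = GAS_CONSTANT
    v_half_inact: float = -45.0  # mV, L-type slow-inactivation half-voltage
    k_inact: float = 14.0       # mV, inactivation slope
    tau_inact: float = 150.0    # ms, L-type slow-inactivation time constant
    tau_ml_min: float = 0.2     # ms, floor on the L-gate time constant
    # synapses
    g_gaba: float = 0.3         # mS/cm^2 peak conductance
    e_gaba: float = -80.0       # mV
    tau_gaba: float = 1.0       # ms
    alpha_gaba: float = 0.5     # ms^-1 receptor binding rate
    v_s: float = 100.0          # mV scaling of the omega-dependent threshold
    v_thr0: float = -40.0       # mV release threshold at omega = 1
    sigma_s: float = 6.0        # mV release sigmoid slope
    release_floor: float = 0.05  # CB1-insensitive fraction of release drive
    g_ampa: float = 10.0        # mS/cm^2
    e_ampa: float = 0.0
    tau_ampa: float = 1.0       # ms

    def validate(self) -> None:
        for name in ("c_m", "g_na", "g_k", "g_l", "p_max_l",
                     "g_gaba", "g_ampa"):
            if getattr(self, name) < 0:
                raise ParameterError(f"postsynaptic.{name} must be >= 0")
        if self.ca_out <= 0:
            raise ParameterError("postsynaptic.ca_out must be > 0")
        for name in ("tau_gaba", "tau_ampa", "sigma_s", "alpha_gaba",
                     "tau_ml_min", "k_inact", "tau_inact"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"postsynaptic.{name} must be > 0")
        for name in ("t_exp", "t_sim"):
            t = getattr(self, name)
            if not (0.0 <= t <= 45.0):
                raise ParameterError(f"postsynaptic.{name} outside 0-45 C")
        if not (0.0 <= self.release_floor < 1.0):
            raise ParameterError("postsynaptic.release_floor must be in [0, 1)")

    @property
    def temperature_k(self) -> float:
        return self.t_sim + 273.15


@dataclass
class SignallingParameters:
    """Cytosol/ER calcium, DAG production and 2-AG synthesis/oxidation.

    Rates are per second.  nu0 (constant plasma-membrane influx) defaults to
    the value balancing the PMCA pump at the 0.02 uM basal calcium fixed
    point; set it explicitly to move the basal point.
    """

    eps_pm: float = 1.0          # strength of plasma-membrane fluxes
    nu0: Optional[float] = None  # uM/s constant influx (None -> basal balance)
    rho: float = 0.185           # effective volume ratio ER/cytosol
    v_serca: float = 0.0545       # uM/s maximal SERCA rate
    k_serca: float = 0.1         # uM
    v_pmca: float = 0.0782        # uM/s maximal PMCA rate
    k_pmca: float = 0.12         # uM
    nu_leak: float = 0.015       # s^-1 ER leak rate
    ca_basal: float = 0.02       # uM basal cytosolic calcium
    v_dag: float = 10.0          # uM/s maximal Ca-evoked DAG synthesis
    k_dag: float = 0.7           # uM half-activation for DAG synthesis
    k_dag_deg: float = 0.66      # s^-1 DAG degradation
    k_syn: float = 0.5           # s^-1 2-AG synthesis (DGL-alpha)
    k_deg_ag: float = 2.0        # uM^-1 s^-1 2-AG oxidation rate constant
    cox2: float = 1.0            # uM, constant COX-2 availability
    ag_max: float = 50.0         # uM ceiling on total mobilisable 2-AG
    beta_buf: float = 0.01       # fast-buffering factor (fraction free)
    radius: float = 10.0         # um, spherical soma radius

    def validate(self) -> None:
        for name in ("v_serca", "v_pmca", "nu_leak", "v_dag", "k_dag_deg",
                     "k_syn", "k_deg_ag", "cox2", "eps_pm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"signalling.{name} must be >= 0")
        for name in ("k_serca", "k_pmca", "k_dag", "ag_max", "ca_basal"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"signalling.{name} must be > 0")
        if not (0.0 < self.beta_buf <= 1.0):
            raise ParameterError("signalling.beta_buf must be in (0, 1]")
        if self.radius <= 0:
            raise ParameterError("signalling.radius must be > 0")
        if self.nu0 is not None and self.nu0 < 0:
            raise ParameterError("signalling.nu0 must be >= 0")

    def nu0_effective(self) -> float:
        """Constant influx; defaults to the PMCA balance at basal calcium."""
        if self.nu0 is not None:
            return self.nu0
        c = self.ca_basal
        return self.v_pmca * c * c / (c * c + self.k_pmca * self.k_pmca)


@dataclass
class IntegratorSettings:
    """Fixed-step RK4 settings.

    dt must resolve the HH spike (<= 0.05 ms).  The model is deterministic;
    ``seed`` is accepted for interface uniformity and never consumed.
    """

    dt: float = 0.02             # ms
    method: str = "rk4"
    record_dt: float = 1.0       # ms between recorded samples
    settle: float = 2.0          # s of stimulus-free settling prepended
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.dt <= 0:
            raise ParameterError("integrator.dt must be > 0")
        if self.dt > 0.05:
            raise ParameterError("integrator.dt must be <= 0.05 ms")
        if self.method not in ("rk4", "reference"):
            raise ParameterError("integrator.method must be rk4 or reference")
        if self.record_dt < self.dt:
            raise ParameterError("integrator.record_dt must be >= dt")


@dataclass
class ModelParameters:
    """The complete validated parameter set."""

    presynaptic: PresynapticParameters = field(default_factory=PresynapticParameters)
    cb1: CB1Parameters = field(default_factory=CB1Parameters)
    postsynaptic: PostsynapticParameters = field(default_factory=PostsynapticParameters)
    signalling: SignallingParameters = field(default_factory=SignallingParameters)
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)

    def validate(self) -> "ModelParameters":
        self.presynaptic.validate()
        self.cb1.validate()
        self.postsynaptic.validate()
        self.signalling.validate()
        self.integrator.validate()
        return self

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        groups = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(d) - set(groups)
        if unknown:
            raise ParameterError(f"unknown parameter group(s): {sorted(unknown)}")
        kwargs = {}
        for name, f in zip(groups, dataclasses.fields(cls)):
            sub = d.get(name, {})
            subcls = f.default_factory
            valid = {sf.name for sf in dataclasses.fields(subcls)}
            bad = set(sub) - valid
            if bad:
                raise ParameterError(f"unknown key(s) in {name}: {sorted(bad)}")
            kwargs[name] = subcls(**sub)
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **dotted) -> "ModelParameters":
        """Return a copy with dotted-path overrides, e.g.
        ``replace(**{"signalling.beta_buf": 0.02})``."""
        d = self.to_dict()
        for key, value in dotted.items():
            group, _, leaf = key.partition(".")
            if not leaf or group not in d or leaf not in d[group]:
                raise ParameterError(f"unknown parameter {key!r}")
            d[group][leaf] = value
        return ModelParameters.from_dict(d)


def default_parameters() -> ModelParameters:
    return ModelParameters().validate()


# ---------------------------------------------------------------------------
# flat packing for the integration kernel (all rates on the ms time base)
# ---------------------------------------------------------------------------
_PACK_NAMES = (
    # presynaptic
    "PRE_CM", "PRE_GNA", "PRE_ENA", "PRE_GK", "PRE_EK", "PRE_GL", "PRE_EL",
    "PRE_PHI",
    # cb1
    "KP_MAX", "KM_MAX", "KGHALF", "VHALF_KP", "KSLOPE", "TAU_KP", "IMAX_AG", "IMAX_WIN",
    "EC50_AG", "EC50_WIN", "NHILL", "TAU_G", "F_MGL",
    # postsynaptic electrical
    "POST_CM", "POST_GNA", "POST_ENA", "POST_GK", "POST_EK", "POST_GL",
    "POST_EL", "POST_VT", "POST_PHI",
    # VGCC
    "PMAXL", "CAOUT", "ZFRT", "PZF", "VH_INACT", "K_INACT", "TAU_INACT", "TAU_ML_MIN",
    # synapses
    "GGABA", "EGABA", "TAUGABA", "ALPHAGABA", "V_S", "V_THR0", "SIGMA_S",
    "REL_FLOOR",
    "GAMPA", "EAMPA", "TAUAMPA",
    # signalling (ms base)
    "EPS_PM", "NU0", "RHO", "VSERCA", "KSERCA2", "VPMCA", "KPMCA2",
    "NULEAK", "VDAG", "KDAG2", "KDAGDEG", "KSYN", "KDEGAG_COX", "AGMAX",
    "KAPPA",
)
_PIDX = {name: i for i, name in enumerate(_PACK_NAMES)}
globals().update(_PIDX)
NPARAM = len(_PACK_NAMES)


def phi_temperature(t_exp: float, t_sim: float, q10: float) -> float:
    """Q10 temperature factor multiplying all gating rates."""
    if q10 <= 0:
        raise ParameterError("q10 must be > 0")
    if not (0.0 <= t_exp <= 45.0 and 0.0 <= t_sim <= 45.0):
        raise ParameterError("temperatures outside 0-45 C")
    return float(q10 ** ((t_sim - t_exp) / 10.0))


def flux_conversion_factor(radius_um: float, beta_buf: float,
                           z: float = 2.0, faraday: float = FARADAY) -> float:
    """Current-to-flux factor kappa in (uM/s) per (uA/cm^2).

    J = -kappa * I_Ca for a spherical compartment: kappa =
    beta * (S/V) / (z F) with S/V = 3/r, including the unit bridge
    uA/cm^2 -> uM/s.  Inward (negative) current yields positive influx.
    """
    if radius_um <= 0:
        raise ParameterError("radius must be > 0")
    return beta_buf * 3.0e7 / (z * faraday * radius_um)


def pack_parameters(mp: ModelParameters) -> np.ndarray:
    """Flatten a validated parameter set into the kernel vector.

    All signalling rates are converted from s^-1 to ms^-1 here so the kernel
    runs on a single time base.
    """
    mp.validate()
    pre, cb1, post, sig = mp.presynaptic, mp.cb1, mp.postsynaptic, mp.signalling
    p = np.zeros(NPARAM)
    p[_PIDX["PRE_CM"]] = pre.c_m
    p[_PIDX["PRE_GNA"]] = pre.g_na
    p[_PIDX["PRE_ENA"]] = pre.e_na
    p[_PIDX["PRE_GK"]] = pre.g_k
    p[_PIDX["PRE_EK"]] = pre.e_k
    p[_PIDX["PRE_GL"]] = pre.g_l
    p[_PIDX["PRE_EL"]] = pre.e_l
    p[_PIDX["PRE_PHI"]] = phi_temperature(pre.t_exp, pre.t_sim, pre.q10)

    p[_PIDX["KP_MAX"]] = cb1.k_plus_max
    p[_PIDX["KM_MAX"]] = cb1.k_minus_max
    p[_PIDX["KGHALF"]] = cb1.k_g_half
    p[_PIDX["VHALF_KP"]] = cb1.v_half_kplus
    p[_PIDX["KSLOPE"]] = cb1.k_slope
    p[_PIDX["TAU_KP"]] = cb1.tau_kplus
    p[_PIDX["IMAX_AG"]] = cb1.i_max_ag
    p[_PIDX["IMAX_WIN"]] = cb1.i_max_win
    p[_PIDX["EC50_AG"]] = cb1.ec50_ag
    p[_PIDX["EC50_WIN"]] = cb1.ec50_win
    p[_PIDX["NHILL"]] = cb1.n_hill
    p[_PIDX["TAU_G"]] = cb1.tau_g
    p[_PIDX["F_MGL"]] = cb1.f_mgl

    p[_PIDX["POST_CM"]] = post.c_m
    p[_PIDX["POST_GNA"]] = post.g_na
    p[_PIDX["POST_ENA"]] = post.e_na
    p[_PIDX["POST_GK"]] = post.g_k
    p[_PIDX["POST_EK"]] = post.e_k
    p[_PIDX["POST_GL"]] = post.g_l
    p[_PIDX["POST_EL"]] = post.e_l
    p[_PIDX["POST_VT"]] = post.v_t
    p[_PIDX["POST_PHI"]] = phi_temperature(post.t_exp, post.t_sim, post.q10)

    rt = post.gas_constant * post.temperature_k
    p[_PIDX["PMAXL"]] = post.p_max_l
    p[_PIDX["CAOUT"]] = post.ca_out
    p[_PIDX["ZFRT"]] = post.z * post.faraday / rt          # per volt
    p[_PIDX["PZF"]] = post.z * post.faraday                 # C/mol
    p[_PIDX["VH_INACT"]] = post.v_half_inact
    p[_PIDX["K_INACT"]] = post.k_inact
    p[_PIDX["TAU_INACT"]] = post.tau_inact
    p[_PIDX["TAU_ML_MIN"]] = post.tau_ml_min

    p[_PIDX["GGABA"]] = post.g_gaba
    p[_PIDX["EGABA"]] = post.e_gaba
    p[_PIDX["TAUGABA"]] = post.tau_gaba
    p[_PIDX["ALPHAGABA"]] = post.alpha_gaba
    p[_PIDX["V_S"]] = post.v_s
    p[_PIDX["V_THR0"]] = post.v_thr0
    p[_PIDX["SIGMA_S"]] = post.sigma_s
    p[_PIDX["REL_FLOOR"]] = post.release_floor
    p[_PIDX["GAMPA"]] = post.g_ampa
    p[_PIDX["EAMPA"]] = post.e_ampa
    p[_PIDX["TAUAMPA"]] = post.tau_ampa

    ms = 1e-3  # s^-1 -> ms^-1
    p[_PIDX["EPS_PM"]] = sig.eps_pm
    p[_PIDX["NU0"]] = sig.nu0_effective() * ms
    p[_PIDX["RHO"]] = sig.rho
    p[_PIDX["VSERCA"]] = sig.v_serca * ms
    p[_PIDX["KSERCA2"]] = sig.k_serca ** 2
    p[_PIDX["VPMCA"]] = sig.v_pmca * ms
    p[_PIDX["KPMCA2"]] = sig.k_pmca ** 2
    p[_PIDX["NULEAK"]] = sig.nu_leak * ms
    p[_PIDX["VDAG"]] = sig.v_dag * ms
    p[_PIDX["KDAG2"]] = sig.k_dag ** 2
    p[_PIDX["KDAGDEG"]] = sig.k_dag_deg * ms
    p[_PIDX["KSYN"]] = sig.k_syn * ms
    p[_PIDX["KDEGAG_COX"]] = sig.k_deg_ag * sig.cox2 * ms
    p[_PIDX["AGMAX"]] = sig.ag_max
    p[_PIDX["KAPPA"]] = flux_conversion_factor(
        sig.radius, sig.beta_buf, post.z, post.faraday) * ms
    return p
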