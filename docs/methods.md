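# Methods

## Scope

`ecbdsi` simulates a single CCK-positive basket-cell → CA1 pyramidal-cell
connection during depolarisation-induced suppression of inhibition (DSI) and
its pharmacological counterpart (eCB-iSTD under bath CB1 agonist).  The
model is a minimal kinetic description of the cascade

depolarisation → L-type Ca²⁺ influx → DAG → 2-AG → CB1/G-protein →
reluctant N-type channels → reduced GABA release,

deliberately excluding network interactions, metabotropic (mGluR/mAChR)
routes to 2-AG mobilisation, NMDA-receptor-driven mobilisation, IP₃/ryanodine
store release beyond a passive ER leak, explicit MGL/COX-2 enzyme kinetics
(both are constants), and long-term plasticity.

## State and equations

Nineteen ODE states on a single millisecond time base:

| block | states | notes |
|---|---|---|
| interneuron | V_pre, h_pre, n_pre | Wang–Buzsáki kinetics, m = m∞, φ = q10^((T_sim−T_exp)/10) = 5 |
| CB1 cascade | ω, G, V_f | dG/dt = (H_AG+H_WIN − G)/τ_G; dω/dt = k₊(V_f)(1−ω) − k₋_max·G·ω |
| pyramidal cell | V_post, h_post, n_post, m_L, h_L | Traub/Huguenard kinetics (V_T = −55 mV), m = m∞ |
| signalling | Ca_c, Ca_ER, DAG, AG, P | see below |
| synapses | s_GABA, s_AMPA, x_AMPA | x is the auxiliary state of the AMPA alpha function |

V_f is the presynaptic voltage low-pass filtered with τ = 0.5 ms (the finite
rate of voltage-driven Gβγ unbinding); at the default it is essentially V_pre.

Calcium and 2-AG (concentrations µM, rates s⁻¹ at the user surface):

    dCa_c/dt  = J_ch + ν_leak(Ca_ER − Ca_c) − J_SERCA + ε(ν₀ − J_PMCA)
    dCa_ER/dt = (J_SERCA − ν_leak(Ca_ER − Ca_c))/ρ
    dDAG/dt   = V_DAG·Hill₂(Ca_c; K_DAG) − k_deg^DAG·DAG − R₁
    dAG/dt    = R₁ − R₂,   dP/dt = R₂
    R₁ = k_syn·DAG·(1 − (AG+P)/AG_max),   R₂ = k_ox·[COX2]·AG

with Hill-2 pumps, J_ch = −κ·I_Ca, κ = β·(3/r)/(zF) in consistent units
(recomputed from fundamental constants and asserted at every integration).
d(AG+P)/dt = R₁ exactly: the 2-AG/product pair is closed bookkeeping against
the AG_max = 50 µM mobilisable pool.  ν₀ defaults to the PMCA balance that
makes Ca_c = 0.02 µM the exact basal fixed point.

GABA release couples the cells without explicit transmitter kinetics:

    ds/dt = α·F(V_pre; ω)(1−s) − s/τ_s
    F = (1−f₀)·σ((V_pre − V_thr(ω))/σ_s) + f₀·σ((V_pre − V_thr0)/σ_s)
    V_thr(ω) = V_thr0 + V_s(1−ω)

A fraction f₀ = 0.05 of the release drive is CB1-insensitive (it keeps the
ω = 1 threshold): reluctant channels still support a little release under
strong depolarisation, which is what caps maximal suppression near 93–95%
rather than 100% — consistent with the sub-unity maximal-inhibition
parameters of the concentration–response curves (I_max 0.5 / 0.48).

## Parameters

Literature-anchored values (all exposed in the YAML-serialisable config):
WB and Traub/Huguenard conductances and kinetics; L-type maximum
permeability 2.75·10⁻⁴ cm/s; Ca_out 2000 µM; ρ = 0.185; K_SERCA 0.1 µM,
K_PMCA 0.12 µM; DAG degradation 0.66 s⁻¹; V_DAG 10 µM/s with K_DAG 0.7 µM;
k_syn 0.5 s⁻¹; AG_max 50 µM; COX2 1 µM; β = 0.01 (0.02 in the slice-style
Protocol 3); r = 10 µm; GABA_A g = 0.3 mS/cm², E = −80 mV, τ = 1 ms; AMPA
g = 10 mS/cm², E = 0 mV, τ = 1 ms, alpha-function kernel with unit peak;
V_s = 100 mV; k₊ ceiling 0.3 ms⁻¹; k₋ scale 0.0006 ms⁻¹; Hill coefficient
1.2 with EC₅₀ 0.48 µM (2-AG) and 0.002 µM (WIN55,212); I_max 0.5 / 0.48;
τ_G = 1000 ms; MGL survival fraction f_MGL = 1.

Constants the sources leave open were fixed once, as the package's defaults,
against the cascade's macroscopic behaviour (basal calcium 0.02 µM, calcium
decay τ ≈ 5.4 s, DSI peak ≈ 90%, DSI decay τ ≈ 13 s, eCB-iSTD asymptote
≈ 93%):

* SERCA/PMCA maxima 0.0545 / 0.0782 µM/s and ER leak 0.015 s⁻¹ — set the
  calcium decay constant;
* 2-AG oxidation k_ox·[COX2] = 2 s⁻¹ — makes 2-AG track DAG so the CB1 drive
  follows the calcium transient;
* k₊ sigmoid: half-voltage +14 mV, slope 11.15 mV — k₊(−80 mV) ≈ 7·10⁻⁵ ms⁻¹
  sets the slow DSI recovery, k₊ at spike voltages is large so presynaptic
  firing relieves the inhibition;
* release sigmoid: V_thr0 = −40 mV, σ_s = 6 mV, α = 0.5 ms⁻¹ (the linear
  binding regime; faster binding saturates the bound fraction and compresses
  the measurable suppression);
* L-type slow inactivation: half-voltage −45 mV, slope 14 mV, τ = 150 ms.
  This gate is what reconciles step- and train-induction: a 5 s step
  self-limits its own influx while 5 ms spikes at 10–50 Hz arrive on
  non-inactivated channels.

## Stimulation protocols and the DSI measure

All protocols share one timeline: a 2 s quiet lead-in, release test events
every 5 s (0.2 Hz), the conditioning stimulus ending at t = 27 s, and a 30 s
observation window.  The test grid is phased so that post-stimulus events
fall 0.92, 5.92, 10.92 … s after stimulus end, the phase of the source
experiments.  Clamped protocols (1–4) evoke release with 2 ms steps of the
presynaptic command from −80 (−70 in Protocol 3) to 0 mV — read as an
"80 mV depolarisation" of the holding potential; current-clamp protocols
(5–8) use 2 ms, 25 µA/cm² pulses that fire one interneuron spike each.

DSI = 100 − 100·(min post-stimulus amplitude)/(mean baseline amplitude);
Protocol 3 also supports the convention that averages the first two
post-stimulus events.  Negative DSI (potentiation) is reported as-is (with a
flag, clipped at −50).  Decay constants are least-squares single-exponential
fits (free amplitude, fixed floor) from the extremum: for DSI, from the
minimum event toward the 100% baseline; for calcium, from the peak toward
the pre-stimulus level.  The peak-DSI latency is reported both from stimulus
onset and from offset; the offset-referenced value is the headline one,
since the cascade (G lags 2-AG by τ_G = 1 s) necessarily bottoms at the
*second* post-stimulus test event, 5.92 s after the step ends.

Protocol 8's burst amplitude on the postsynaptic cell is 6.0 µA/cm² — just
above the 5–6 µA/cm² rheobase for a 5 ms pulse — so that coincident IPSPs
can actually gate postsynaptic firing, which is the point of the protocol; a
strongly suprathreshold drive would make the coincidence experiment vacuous.

## Numerics

Fixed-step classical RK4, dt = 0.02 ms (HH spikes need ≲ 0.05 ms; the
signalling states are slow and impose no constraint); a `reference` mode
runs at dt/2 for convergence oracles.  All stimulus edges are snapped to the
integration grid and drives are sample-and-hold within a step, so RK4 keeps
its order away from switching instants.  Voltage clamp is algebraic pinning
(dV/dt = 0, V set to the command; state continuous at release).  The GHK
flux uses a fourth-order series through the removable singularity at V = 0
(|zFV/RT| < 10⁻⁴).  The L-gate time constant is floored at 0.2 ms for
stiffness (only active at voltages where the gate is closed anyway).
Initial conditions are computed analytically: clamped potentials as given,
free potentials from the self-consistent resting balance including the
standing synaptic and L-type window currents, calcium at the basal fixed
point (ER at the leak/SERCA balance), and ω, G, s at their steady values.
Evoked-IPSP amplitudes are tracked inside the integration loop at full step
resolution (peak within 20 ms of each release event, onset-subtracted), not
from the down-sampled traces.

All headline quantities change by < 0.1% between dt = 0.02 and 0.01 ms.
Identical runs are bit-identical; no randomness exists in the production
path.

## What the simulations show — and don't

The protocol suite emulates idealised paired recordings: noiseless clamps,
perfectly periodic test pulses, a point-compartment cell.  Passing tests
therefore demonstrate the internal consistency of the cascade and its
parameterisation, not quantitative agreement with any particular slice or
culture preparation; in real data IPSP amplitudes fluctuate, release is
stochastic, and dendritic geometry shapes the calcium signal.

Known limitations:

* The presynaptic-firing modulation of DSI is reproduced qualitatively but
  not in full: with the adopted rate constants, the fast-spiking
  interneuron's narrow spike (~0.5 ms above 0 mV) bounds the per-spike
  relief of N-channel inhibition.  At default parameters, 50 Hz firing
  abolishes DSI (< 10%) but 10 Hz leaves a ~20% transient; in the
  low-k₊ variant (k₊ ceiling 0.005 ms⁻¹ with β = 0.1), DSI is preserved at
  10 Hz but is only partially reduced — not abolished — at 50 Hz.
* Maximal suppression is capped by the CB1-insensitive release fraction;
  manipulations that would push suppression beyond ~95% saturate.
* The ω = 1 resting point entails a tiny standing GABA drive (~3% of an
  evoked event) because the release sigmoid is not exactly zero at rest.
* The oxidised 2-AG product P accumulates without a sink (closed
  bookkeeping), so the basal state drifts on the 10⁻⁵/s scale; over
  minutes-long simulations this consumes a negligible fraction of the 50 µM
  pool.
* Protocol 3's presynaptic pulse width is taken as 2 ms (unstated in the
  source conventions for that protocol).
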