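"""Stimulation protocols, IPSP-event detection, the DSI/eCB-iSTD measure
and decay-constant fitting.

All protocols share a common timeline: a 2 s quiet lead-in, release test
pulses every 5 s (0.2 Hz, the standard paired-recording test rate), the
conditioning stimulus ending at t = 27 s with the test grid phased so that
post-stimulus events fall 0.92, 5.92, 10.92 ... s after stimulus end, and a
30 s post-stimulus observation window.  Release test pulses step the clamped
presynaptic cell to 0 mV for 2 ms (an 80 mV depolarisation from the -80 mV
holding potential) or, in current-clamp protocols, drive it with a 2 ms
suprathreshold current pulse.

The suppression statistic is
    Amp = 100 * (minimum post-stimulus IPSP) / (mean pre-stimulus IPSP),
    DSI = 100 - Amp,
with the IPSP amplitude read from the per-event peak of the bound GABA_A
receptor fraction.  ``wang_first2`` instead averages the first two
post-stimulus events (the convention of slice studies that sample
immediately after the pulse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .params import ModelParameters, IntegratorSettings
from .stimulus import StimulusProgram, PulseTrain, SynapticTrain, BathSegment
from .engine import SimulationResult, integrate

__all__ = [
    "DSIResult", "MeasureError", "detect_ipsp_events", "dsi_measure",
    "fit_exponential_decay", "run_protocol", "ProtocolResult",
    "PROTOCOL_IDS",
]

PROTOCOL_IDS = (1, 2, 3, 4, 5, 6, 7, 8)

# timeline constants (s)
SETTLE = 2.0
TEST_PERIOD = 5.0          # 0.2 Hz test stimulation
FIRST_TEST = 2.92          # phase puts a test event 0.92 s after stimulus end
STIM_END = 27.0            # conditioning stimulus always ends here
POST_WINDOW = 30.0         # observation window after stimulus end
PULSE_AMP = 25.0           # uA/cm^2 suprathreshold pulse amplitude
PRE_PULSE_MS = 2.0
POST_PULSE_MS = 5.0
RELEASE_V = 0.0            # mV, presynaptic release-pulse level


class MeasureError(ValueError):
    """Raised when the DSI measure is undefined for the given events."""


@dataclass
class DSIResult:
    """Evoked-event amplitudes and the derived suppression statistics."""

    ipsp_events: List[Tuple[float, float]]      # (time s, amplitude)
    baseline_avg: float
    post_min: float
    amp_percent: float
    dsi_percent: float
    dsi_timecourse: List[Tuple[float, float]]   # (time from onset s, amp %)
    tau_dsi: float = float("nan")               # s
    tau_ca: float = float("nan")                # s
    peak_dsi_percent: float = float("nan")
    peak_latency: float = float("nan")          # s from stimulus onset
    peak_latency_from_offset: float = float("nan")  # s from stimulus end
    potentiation: bool = False
    mode: str = "standard"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "baseline_avg", "post_min", "amp_percent", "dsi_percent",
            "tau_dsi", "tau_ca", "peak_dsi_percent", "peak_latency",
            "peak_latency_from_offset", "potentiation", "mode")}
        d["ipsp_events"] = [list(e) for e in self.ipsp_events]
        d["dsi_timecourse"] = [list(e) for e in self.dsi_timecourse]
        return d


def detect_ipsp_events(s_trace: np.ndarray, t: np.ndarray,
                       pre_spike_times: np.ndarray,
                       window_s: float = 0.020) -> np.ndarray:
    """Per-event IPSP amplitudes from a recorded s_gaba trace.

    For each presynaptic release time, the amplitude is the peak of the
    bound-receptor fraction within ``window_s`` after the event, minus the
    value at event onset.  Empty spike list gives an empty result.
    """
    pre_spike_times = np.asarray(pre_spike_times, dtype=float)
    if pre_spike_times.size == 0:
        return np.zeros(0)
    if np.any(pre_spike_times < t[0] - 1e-9) or np.any(pre_spike_times > t[-1] + 1e-9):
        raise ValueError("spike times outside trace span")
    amps = np.empty(pre_spike_times.size)
    for i, t0 in enumerate(pre_spike_times):
        j0 = int(np.searchsorted(t, t0 - 1e-12))
        j1 = int(np.searchsorted(t, t0 + window_s + 1e-12))
        seg = s_trace[j0:max(j1, j0 + 1)]
        amps[i] = float(seg.max() - s_trace[j0])
    return amps


def fit_exponential_decay(times: np.ndarray, values: np.ndarray,
                          floor: float) -> float:
    """Least-squares single-exponential fit from the initial extremum
    towards ``floor``; returns the time constant (same units as ``times``).

    A constant series returns ``inf`` (no decay); a series that is not
    decay-dominated still returns the best-fit tau but emits a
    fit-quality warning with diagnostics.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 5:
        raise ValueError("need at least 5 points for a decay fit")
    v0 = values[0]
    if np.allclose(values, values[0], rtol=0, atol=1e-12 + 1e-9 * abs(v0)):
        return float("inf")
    span = v0 - floor
    if span == 0:
        return float("inf")

    def model(t, tau, amp):
        return floor + amp * np.exp(-(t - times[0]) / tau)

    tau0 = max((times[-1] - times[0]) / 3.0, 1e-6)
    lo, hi = sorted((0.0, 2.0 * span))
    popt, _ = curve_fit(model, times, values, p0=[tau0, span],
                        bounds=([1e-9, lo], [np.inf, hi]), maxfev=10000)
    tau = float(popt[0])
    resid = values - model(times, tau, float(popt[1]))
    ss = float(np.sum(resid ** 2))
    tot = float(np.sum((values - values.mean()) ** 2))
    if tot > 0 and ss / tot > 0.5:
        warnings.warn(
            f"exponential fit explains only {100 * (1 - ss / tot):.1f}% of "
            f"variance (tau = {tau:.3g}); series may not be decay-dominated",
            RuntimeWarning, stacklevel=2)
    return tau


def dsi_measure(event_times: np.ndarray, amplitudes: np.ndarray,
                stim_onset: float, stim_end: float,
                mode: str = "standard",
                post_until: Optional[float] = None) -> DSIResult:
    """The DSI / eCB-iSTD statistic from evoked-event amplitudes.

    Baseline events precede ``stim_onset``; post events follow ``stim_end``
    (optionally bounded by ``post_until``).  ``standard`` uses the minimum
    post-stimulus amplitude, ``wang_first2`` the mean of the first two
    post-stimulus events.
    """
    if mode not in ("standard", "wang_first2"):
        raise ValueError(f"unknown DSI mode {mode!r}")
    event_times = np.asarray(event_times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    base_mask = event_times < stim_onset - 1e-9
    post_mask = event_times > stim_end + 1e-9
    if post_until is not None:
        post_mask &= event_times <= post_until + 1e-9
    if base_mask.sum() < 1 or post_mask.sum() < 1:
        raise MeasureError("need at least one baseline and one post event")
    baseline = float(amplitudes[base_mask].mean())
    if baseline <= 0:
        raise MeasureError("zero baseline amplitude; measure undefined")
    post_t = event_times[post_mask]
    post_a = amplitudes[post_mask]
    if mode == "wang_first2":
        k = min(2, post_a.size)
        ref = float(post_a[:k].mean())
        t_ref = float(post_t[:k][np.argmin(post_a[:k])])
    else:
        imin = int(np.argmin(post_a))
        ref = float(post_a[imin])
        t_ref = float(post_t[imin])
    amp_percent = 100.0 * ref / baseline
    dsi = 100.0 - amp_percent
    potentiation = dsi < 0
    timecourse = [(float(t - stim_onset), float(100.0 * a / baseline))
                  for t, a in zip(event_times, amplitudes)]
    res = DSIResult(
        ipsp_events=[(float(t), float(a)) for t, a in zip(event_times, amplitudes)],
        baseline_avg=baseline,
        post_min=float(post_a.min()),
        amp_percent=amp_percent,
        dsi_percent=float(max(dsi, -50.0)),
        dsi_timecourse=timecourse,
        peak_dsi_percent=float(100.0 - 100.0 * post_a.min() / baseline),
        peak_latency=t_ref - stim_onset,
        peak_latency_from_offset=t_ref - stim_end,
        potentiation=potentiation,
        mode=mode,
    )
    # decay constant of the DSI time course, from the minimum event onward
    rec_t = post_t[post_t >= t_ref - 1e-9]
    rec_a = 100.0 * post_a[post_t >= t_ref - 1e-9] / baseline
    if rec_t.size >= 5:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res.tau_dsi = fit_exponential_decay(rec_t, rec_a, floor=100.0)
    return res


def fit_calcium_decay(sim: SimulationResult, stim_onset: float,
                      stim_end: float, window: float = 25.0) -> float:
    """Exponential decay constant (s) of cytosolic calcium from its peak."""
    t = sim.t
    ca = sim.trace("ca_c")
    pre = ca[t < stim_onset]
    baseline = float(pre[-1]) if pre.size else float(ca[0])
    mask = (t >= stim_onset) & (t <= stim_end + window)
    tt, cc = t[mask], ca[mask]
    ipk = int(np.argmax(cc))
    return fit_exponential_decay(tt[ipk:], cc[ipk:], floor=baseline)


@dataclass
class ProtocolResult:
    protocol: int
    sim: SimulationResult
    dsi: DSIResult
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# protocol factories
# ---------------------------------------------------------------------------

def _test_events(until: float, start: float = FIRST_TEST) -> np.ndarray:
    return np.arange(start, until, TEST_PERIOD)


def _clamped_pre(prog: StimulusProgram, v_hold: float, events: np.ndarray):
    prog.hold("pre", v_hold)
    for t in events:
        prog.clamp_pulse("pre", RELEASE_V, float(t), PRE_PULSE_MS, measure=True)


def _pulsed_pre(prog: StimulusProgram, events: np.ndarray,
                measure: bool = True):
    for t in events:
        prog.pulses.append(PulseTrain("pre", PULSE_AMP, PRE_PULSE_MS, float(t)))
        if measure:
            prog.measure_events.append(float(t))


def build_program(protocol: int, *, duration: float = 5.0,
                  freq: float = 10.0, win: float = 5.0,
                  mode: str = "pulses", pre_freq: float = 0.2,
                  lag: float = 0.0, burst: float = 1.0) -> StimulusProgram:
    """Construct the stimulus program for one of the eight protocols."""
    if protocol not in PROTOCOL_IDS:
        raise ValueError(f"unknown protocol {protocol}")

    if protocol == 1:
        total = STIM_END - 2.0 + 60.0 + 1.0  # application starts at 25 s
        prog = StimulusProgram(duration=total)
        app0 = 25.0
        prog.hold("post", -80.0)
        _clamped_pre(prog, -80.0, _test_events(total - 0.5))
        prog.bath.append(BathSegment(win, app0, app0 + 60.0))
        return prog.validate()

    if protocol in (2, 3, 4):
        v_hold = -70.0 if protocol == 3 else -80.0
        onset = STIM_END - duration
        if onset <= FIRST_TEST + TEST_PERIOD:
            raise ValueError("depolarisation too long for the baseline epoch")
        total = STIM_END + POST_WINDOW + 1.0
        prog = StimulusProgram(duration=total)
        prog.hold("post", v_hold)
        prog.clamp_pulse("post", 0.0, onset, duration * 1000.0)
        _clamped_pre(prog, v_hold, _test_events(total - 0.5))
        return prog.validate()

    if protocol == 5:
        onset = STIM_END - duration
        total = STIM_END + POST_WINDOW + 1.0
        prog = StimulusProgram(duration=total)
        _clamped_pre(prog, -80.0, _test_events(total - 0.5))
        if mode == "pulses":
            prog.pulses.append(PulseTrain("post", PULSE_AMP, POST_PULSE_MS,
                                          onset, freq_hz=freq, duration=duration))
        elif mode == "synaptic":
            prog.synaptic.append(SynapticTrain(freq, duration, onset))
        else:
            raise ValueError(f"unknown induction mode {mode!r}")
        return prog.validate()

    if protocol == 6:
        total = STIM_END + POST_WINDOW + 1.0
        if mode == "win":
            total = 25.0 + 60.0 + 1.0
        prog = StimulusProgram(duration=total)
        n = int(np.floor((total - 3.0 - FIRST_TEST) * pre_freq)) + 1
        events = FIRST_TEST + np.arange(n) / pre_freq
        _pulsed_pre(prog, events)
        if mode == "win":
            prog.bath.append(BathSegment(win, 25.0, 25.0 + 60.0))
        else:
            prog.hold("post", -80.0)
            prog.clamp_pulse("post", 0.0, STIM_END - duration, duration * 1000.0)
        return prog.validate()

    if protocol == 7:
        total = STIM_END + POST_WINDOW + 1.0
        prog = StimulusProgram(duration=total)
        n = int(np.floor((total - 3.0 - FIRST_TEST) * pre_freq)) + 1
        events = FIRST_TEST + np.arange(n) / pre_freq
        _pulsed_pre(prog, events)
        prog.pulses.append(PulseTrain("post", PULSE_AMP, POST_PULSE_MS,
                                      STIM_END - duration, freq_hz=freq,
                                      duration=duration))
        return prog.validate()

    if protocol == 8:
        # the burst amplitude is adjusted to be just suprathreshold (one
        # action potential per pulse), so that coincident IPSPs can gate
        # postsynaptic firing
        post_amp = 6.0
        post_onset = 19.0
        total = post_onset + burst + POST_WINDOW + 1.0
        prog = StimulusProgram(duration=total)
        _pulsed_pre(prog, _test_events(total - 0.5, start=2.5))
        prog.pulses.append(PulseTrain("post", post_amp, POST_PULSE_MS,
                                      post_onset, freq_hz=freq, duration=burst))
        pre_onset = post_onset + lag
        if pre_onset < 0:
            raise ValueError("pre-synaptic burst would start before t = 0")
        prog.pulses.append(PulseTrain("pre", PULSE_AMP, PRE_PULSE_MS,
                                      pre_onset, freq_hz=freq, duration=burst))
        return prog.validate()

    raise AssertionError("unreachable")


def _stim_bounds(protocol: int, duration: float, mode: str,
                 burst: float) -> Tuple[float, float]:
    if protocol == 1 or (protocol == 6 and mode == "win"):
        return 25.0, 25.0  # post events = during application
    if protocol == 8:
        return 19.0, 19.0 + burst
    return STIM_END - duration, STIM_END


def run_protocol(protocol: int, *, duration: float = 5.0, freq: float = 10.0,
                 win: float = 5.0, mode: Optional[str] = None,
                 pre_freq: float = 0.2, lag: float = 0.0, burst: float = 1.0,
                 dsi_mode: str = "standard",
                 param_overrides: Optional[dict] = None,
                 params: Optional[ModelParameters] = None,
                 settings: Optional[IntegratorSettings] = None) -> ProtocolResult:
    """Build, run and measure one of the eight stimulation protocols.

    ``param_overrides`` maps dotted parameter paths to values, e.g.
    ``{"signalling.beta_buf": 0.02}``.  Protocol 3 additionally defaults the
    buffering factor to 0.02 and supports ``dsi_mode='wang_first2'``.
    """
    params = params or ModelParameters()
    if protocol == 3 and not (param_overrides and
                              "signalling.beta_buf" in param_overrides):
        params = params.replace(**{"signalling.beta_buf": 0.02})
    if param_overrides:
        params = params.replace(**param_overrides)
    if mode is None:
        mode = {5: "pulses", 6: "depol"}.get(protocol, "")
    prog = build_program(protocol, duration=duration, freq=freq, win=win,
                         mode=mode, pre_freq=pre_freq, lag=lag, burst=burst)
    sim = integrate(prog, params, settings)
    onset, end = _stim_bounds(protocol, duration, mode, burst)
    dsi = dsi_measure(sim.event_times, sim.event_amps, onset, end,
                      mode=dsi_mode)
    if protocol in (2, 3, 4):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dsi.tau_ca = fit_calcium_decay(sim, onset, end)
    info = {"stim_onset": onset, "stim_end": end, "mode": mode,
            "duration": duration}
    return ProtocolResult(protocol, sim, dsi, info)
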