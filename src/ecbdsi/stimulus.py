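"""Stimulation programs: voltage clamps, current pulses, synaptic trains and
bath agonist schedules, compiled to step-function arrays for the integrator.

A :class:`StimulusProgram` is a declarative, time-ordered schedule.  Clamp
segments may nest (a 2 ms release pulse inside a long holding clamp); the
latest-starting active segment wins, which is how the release test pulses
override the holding potential.  All times are seconds at the user surface
and are snapped to integrator steps when compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = [
    "ClampSegment", "PulseTrain", "SynapticTrain", "BathSegment",
    "StimulusProgram", "make_fixture", "StimulusError",
]

PRE, POST = "pre", "post"


class StimulusError(ValueError):
    """Raised for inconsistent stimulus programs."""


@dataclass
class ClampSegment:
    cell: str
    v_hold: float          # mV
    t_start: float         # s
    t_end: float           # s


@dataclass
class PulseTrain:
    """Train of rectangular current pulses (single pulse if freq is None)."""
    cell: str
    amplitude: float       # uA/cm^2
    width_ms: float
    onset: float           # s
    freq_hz: Optional[float] = None
    duration: float = 0.0  # s of train (>= one pulse)

    def pulse_times(self) -> np.ndarray:
        if self.freq_hz is None or self.freq_hz <= 0 or self.duration <= 0:
            return np.array([self.onset])
        n = int(math.floor(self.duration * self.freq_hz - 1e-9)) + 1
        return self.onset + np.arange(n) / self.freq_hz


@dataclass
class SynapticTrain:
    """Train of excitatory (AMPA) synaptic events."""
    freq_hz: float
    duration: float        # s
    onset: float           # s

    def event_times(self) -> np.ndarray:
        n = int(math.floor(self.duration * self.freq_hz - 1e-9)) + 1
        return self.onset + np.arange(n) / self.freq_hz


@dataclass
class BathSegment:
    conc: float            # uM WIN55,212
    t_start: float
    t_end: float


@dataclass
class StimulusProgram:
    duration: float                          # s
    clamps: List[ClampSegment] = field(default_factory=list)
    pulses: List[PulseTrain] = field(default_factory=list)
    synaptic: List[SynapticTrain] = field(default_factory=list)
    bath: List[BathSegment] = field(default_factory=list)
    # release events whose evoked IPSP amplitude is measured
    measure_events: List[float] = field(default_factory=list)  # s
    measure_window_ms: float = 20.0

    # -- construction helpers ----------------------------------------------
    def hold(self, cell: str, v: float, t0: float = 0.0,
             t1: Optional[float] = None) -> "StimulusProgram":
        self.clamps.append(ClampSegment(cell, v, t0, self.duration if t1 is None else t1))
        return self

    def clamp_pulse(self, cell: str, v: float, t: float, width_ms: float,
                    measure: bool = False) -> "StimulusProgram":
        self.clamps.append(ClampSegment(cell, v, t, t + width_ms * 1e-3))
        if measure:
            self.measure_events.append(t)
        return self

    def validate(self) -> "StimulusProgram":
        if self.duration <= 0:
            raise StimulusError("duration must be > 0")
        for seg in self.clamps:
            if seg.cell not in (PRE, POST):
                raise StimulusError(f"unknown cell {seg.cell!r}")
            if not (0 <= seg.t_start < seg.t_end <= self.duration + 1e-9):
                raise StimulusError("clamp segment outside program span")
        for tr in self.pulses:
            if tr.cell not in (PRE, POST):
                raise StimulusError(f"unknown cell {tr.cell!r}")
            times = tr.pulse_times()
            if times.size and (times[0] < 0 or
                               times[-1] + tr.width_ms * 1e-3 > self.duration + 1e-9):
                raise StimulusError("pulse train outside program span")
        for tr in self.synaptic:
            ev = tr.event_times()
            if ev.size and (ev[0] < 0 or ev[-1] > self.duration + 1e-9):
                raise StimulusError("synaptic train outside program span")
        for seg in self.bath:
            if not (0 <= seg.t_start < seg.t_end <= self.duration + 1e-9):
                raise StimulusError("bath segment outside program span")
            if seg.conc < 0:
                raise StimulusError("bath concentration must be >= 0")
        for t in self.measure_events:
            if not (0 <= t <= self.duration):
                raise StimulusError("measurement event outside program span")
        if sorted(self.measure_events) != list(self.measure_events):
            raise StimulusError("measurement events must be time-ordered")
        return self

    # -- compilation --------------------------------------------------------
    def _clamp_stepfun(self, cell: str, dt_ms: float):
        segs = [s for s in self.clamps if s.cell == cell]
        edges = {0.0}
        for s in segs:
            edges.add(round(s.t_start * 1000.0 / dt_ms) * dt_ms)
            edges.add(round(s.t_end * 1000.0 / dt_ms) * dt_ms)
        times = np.array(sorted(edges))
        values = np.full(times.size, np.nan)
        for i, t in enumerate(times):
            best = None
            for s in segs:
                t0 = round(s.t_start * 1000.0 / dt_ms) * dt_ms
                t1 = round(s.t_end * 1000.0 / dt_ms) * dt_ms
                if t0 <= t < t1 and (best is None or t0 >= best[0]):
                    best = (t0, s.v_hold)
            if best is not None:
                values[i] = best[1]
        return times, values

    def _current_stepfun(self, cell: str, dt_ms: float):
        trains = [tr for tr in self.pulses if tr.cell == cell]
        edges = {0.0}
        events = []
        for tr in trains:
            for t in tr.pulse_times():
                t0 = round(t * 1000.0 / dt_ms) * dt_ms
                t1 = round((t * 1000.0 + tr.width_ms) / dt_ms) * dt_ms
                events.append((t0, t1, tr.amplitude))
                edges.add(t0)
                edges.add(t1)
        times = np.array(sorted(edges))
        values = np.zeros(times.size)
        for i, t in enumerate(times):
            values[i] = sum(a for (t0, t1, a) in events if t0 <= t < t1)
        return times, values

    def _bath_stepfun(self, dt_ms: float):
        edges = {0.0}
        for s in self.bath:
            edges.add(round(s.t_start * 1000.0 / dt_ms) * dt_ms)
            edges.add(round(s.t_end * 1000.0 / dt_ms) * dt_ms)
        times = np.array(sorted(edges))
        values = np.zeros(times.size)
        for i, t in enumerate(times):
            values[i] = sum(s.conc for s in self.bath
                            if round(s.t_start * 1000.0 / dt_ms) * dt_ms <= t
                            < round(s.t_end * 1000.0 / dt_ms) * dt_ms)
        return times, values

    def compile(self, dt_ms: float) -> dict:
        """Snap the schedule to the integration grid.

        Returns breakpoint arrays (times in ms; clamp value NaN = unclamped),
        AMPA impulse step indices, and the measurement-event schedule.
        """
        self.validate()
        out = {}
        out["cpre_t"], out["cpre_v"] = self._clamp_stepfun(PRE, dt_ms)
        out["cpost_t"], out["cpost_v"] = self._clamp_stepfun(POST, dt_ms)
        out["ipre_t"], out["ipre_v"] = self._current_stepfun(PRE, dt_ms)
        out["ipost_t"], out["ipost_v"] = self._current_stepfun(POST, dt_ms)
        out["win_t"], out["win_v"] = self._bath_stepfun(dt_ms)
        ampa = []
        for tr in self.synaptic:
            ampa.extend(int(round(t * 1000.0 / dt_ms)) for t in tr.event_times())
        out["ampa_steps"] = np.array(sorted(ampa), dtype=np.int64)
        ev = np.asarray(self.measure_events, dtype=float) * 1000.0  # ms
        gaps = np.diff(ev) if ev.size > 1 else np.array([np.inf])
        win = min(self.measure_window_ms, float(gaps.min()) if gaps.size else np.inf)
        out["ev_t"] = ev
        out["ev_win"] = win
        out["n_steps"] = int(round(self.duration * 1000.0 / dt_ms))
        return out


def make_fixture(kind: str, **kw) -> StimulusProgram:
    """Reproducible stimulus programs for tests.

    kinds: ``spike_train`` (current pulses on a cell), ``alpha_events``
    (AMPA synaptic train), ``clamp_step`` (single voltage-clamp step).
    """
    if kind == "spike_train":
        freq = kw.get("freq_hz", 30.0)
        dur = kw.get("duration", 1.0)
        onset = kw.get("onset", 0.1)
        total = kw.get("total", onset + dur + 0.5)
        prog = StimulusProgram(duration=total)
        prog.pulses.append(PulseTrain(
            cell=kw.get("cell", POST), amplitude=kw.get("amplitude", 25.0),
            width_ms=kw.get("width_ms", 5.0), onset=onset,
            freq_hz=freq, duration=dur))
        return prog.validate()
    if kind == "alpha_events":
        freq = kw.get("freq_hz", 50.0)
        dur = kw.get("duration", 0.5)
        onset = kw.get("onset", 0.1)
        total = kw.get("total", onset + dur + 0.5)
        prog = StimulusProgram(duration=total)
        prog.synaptic.append(SynapticTrain(freq_hz=freq, duration=dur, onset=onset))
        return prog.validate()
    if kind == "clamp_step":
        onset = kw.get("onset", 1.0)
        dur = kw.get("duration", 5.0)
        total = kw.get("total", onset + dur + 1.0)
        prog = StimulusProgram(duration=total)
        prog.hold(kw.get("cell", POST), kw.get("v_base", -80.0))
        prog.clamps.append(ClampSegment(kw.get("cell", POST),
                                        kw.get("v_hold", 0.0), onset, onset + dur))
        return prog.validate()
    raise StimulusError(f"unknown fixture kind {kind!r}")
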