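"""Spontaneous synaptic analysis: EPSC detection, statistics, network bursts.

EPSCs are inward deflections on a gap-free voltage-clamp current trace.
The detector estimates baseline and noise robustly (blockwise median and
MAD, interpolated across the recording, so slow drift and a nonzero
holding current do not bias it), thresholds the inward deflection at
``k_sd`` robust standard deviations, locates candidate peaks, and accepts
a candidate only if its 10–90% rise time and decay time constant fall
inside physiological bounds.

Network bursts are maximal runs of at least ``min_events`` events whose
inter-event intervals all stay at or below ``max_isi_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import Trace

__all__ = [
    "SynapticEvent",
    "BurstSummary",
    "detect_events",
    "event_statistics",
    "detect_bursts",
    "KineticBounds",
]

BASELINE_BLOCK_S = 5.0
K_SD_DEFAULT = 3.0
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class KineticBounds:
    """Acceptance window for event kinetics (ms)."""

    rise_min: float = 0.5
    rise_max: float = 5.0
    decay_min: float = 3.0
    decay_max: float = 50.0


@dataclass
class SynapticEvent:
    time_s: float         # peak time
    amplitude_pa: float   # positive magnitude of the inward deflection
    rise_ms: float        # 10–90% rise time
    decay_ms: float       # time to decay to 1/e of the peak


@dataclass
class BurstSummary:
    intervals: list[tuple[float, float]]   # (start, end) of each burst, s
    durations: np.ndarray                  # s
    burst_rate_hz: float                   # bursts / recording duration
    interburst_intervals: np.ndarray       # gaps between consecutive bursts, s
    recording_duration_s: float

    @property
    def n_bursts(self) -> int:
        return len(self.intervals)

    @property
    def mean_duration_s(self) -> float:
        return float(self.durations.mean()) if self.durations.size else np.nan

    @property
    def mean_interburst_s(self) -> float:
        return (float(self.interburst_intervals.mean())
                if self.interburst_intervals.size else np.nan)


def _robust_baseline(x: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Blockwise median baseline (interpolated) and a global robust noise SD."""
    block = max(16, int(round(BASELINE_BLOCK_S * fs)))
    nblocks = max(1, x.size // block)
    used = nblocks * block
    xb = x[:used].reshape(nblocks, block)
    med = np.median(xb, axis=1)
    mad = np.median(np.abs(xb - med[:, None]), axis=1)
    sd = float(np.median(mad) * MAD_TO_SD)
    centers = (np.arange(nblocks) + 0.5) * block
    baseline = np.interp(np.arange(x.size), centers, med)
    return baseline, sd


def _event_kinetics(
    d: np.ndarray, peak: int, fs: float,
    prev_peak: int | None, next_peak: int | None,
) -> tuple[float, float]:
    """10–90% rise (ms) and 1/e decay time (ms) around a peak.

    Both are referenced to the valley preceding the peak (the local
    minimum since the previous event, or the pre-event baseline for an
    isolated event) so stacked events within a burst are measured
    correctly.
    """
    start = prev_peak if prev_peak is not None else max(0, peak - int(0.05 * fs))
    valley = float(d[start:peak + 1].min()) if peak > start else 0.0
    valley = max(valley, 0.0)
    amp = d[peak]
    rel = amp - valley
    if rel <= 0:
        return 0.0, 0.0
    lo = valley + 0.1 * rel
    hi = valley + 0.9 * rel

    def interp(j, level):
        if j + 1 < d.size and d[j + 1] != d[j]:
            return j + (level - d[j]) / (d[j + 1] - d[j])
        return float(j)

    # rise: walk back to the 10% and 90% crossings of the valley→peak excursion
    i = peak
    t90 = None
    while i > start and d[i] > lo:
        if t90 is None and d[i] <= hi:
            t90 = i
        i -= 1
    t10 = i
    if t90 is None:
        t90 = peak
    rise = (interp(t90, hi) - interp(t10, lo)) / fs * 1000.0

    # decay: time from the peak to 1/e of the valley-referenced amplitude,
    # capped at the next event
    stop = next_peak if next_peak is not None else d.size
    j = peak
    level = valley + rel / np.e
    while j < stop - 1 and d[j] > level:
        j += 1
    if d[j] > level:           # never decayed inside the span
        decay = np.inf
    else:
        decay = (interp(j - 1, level) - peak) / fs * 1000.0 if j > peak else 0.0
    return float(max(rise, 0.0)), float(decay)


def detect_events(
    trace: Trace,
    k_sd: float = K_SD_DEFAULT,
    kinetic_bounds: KineticBounds | None = None,
    refractory_ms: float = 2.0,
    smooth_ms: float = 0.6,
) -> list[SynapticEvent]:
    """Detect spontaneous inward synaptic events on a gap-free current trace.

    Candidates are local minima of the baseline-subtracted current whose
    inward deflection exceeds ``k_sd`` × (robust noise SD); each candidate
    must then pass the kinetic acceptance bounds.  Returns events ordered
    by peak time.
    """
    if trace.kind != "current":
        raise ValueError("event detection requires a current trace")
    bounds = kinetic_bounds or KineticBounds()
    if bounds.decay_min <= bounds.rise_min:
        pass  # decay > rise enforced per event below
    fs = trace.fs
    x = trace.samples
    if x.size < 2 * int(BASELINE_BLOCK_S * fs):
        raise ValueError("trace shorter than two baseline windows")
    baseline, sd = _robust_baseline(x, fs)
    d = baseline - x  # inward deflection, positive
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / 1000.0 * fs)))
        kern = np.ones(w) / w
        d_s = np.convolve(d, kern, mode="same")
    else:
        d_s = d
    thr = k_sd * sd if sd > 0 else k_sd * 1e-12
    dist = max(1, int(round(refractory_ms / 1000.0 * fs)))
    peaks, _ = sps.find_peaks(d_s, height=thr, prominence=thr, distance=dist)
    events: list[SynapticEvent] = []
    for idx, pk in enumerate(peaks):
        prv = int(peaks[idx - 1]) if idx > 0 else None
        nxt = int(peaks[idx + 1]) if idx + 1 < peaks.size else None
        rise, decay = _event_kinetics(d_s, int(pk), fs, prv, nxt)
        if not (bounds.rise_min <= rise <= bounds.rise_max):
            continue
        truncated = nxt is not None and not np.isfinite(decay)
        if not truncated and not (
            bounds.decay_min <= decay <= bounds.decay_max and decay > rise
        ):
            continue
        # amplitude read at the smoothed peak: a windowed max over the raw
        # deflection would inherit a max-of-noise bias of several pA
        amp = float(d_s[pk])
        events.append(SynapticEvent(
            time_s=trace.t0 + pk / fs,
            amplitude_pa=amp,
            rise_ms=rise,
            decay_ms=float(decay) if np.isfinite(decay) else np.nan,
        ))
    return events


def event_statistics(
    events: list[SynapticEvent] | np.ndarray,
    duration_s: float,
) -> dict:
    """Rate, amplitude mean ± SEM, and the amplitude ECDF.

    ``events`` may be a list of :class:`SynapticEvent` or a plain array of
    amplitudes.  An empty list gives rate 0 and undefined (NaN) amplitude
    statistics.  The ECDF is returned as a right-continuous step function
    evaluator plus its support.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if len(events) and isinstance(events[0], SynapticEvent):
        amps = np.array([e.amplitude_pa for e in events])
    else:
        amps = np.asarray(events, dtype=float)
    n = amps.size
    rate = n / duration_s
    if n == 0:
        return {"n": 0, "rate_hz": 0.0, "mean_amplitude_pa": np.nan,
                "sem_amplitude_pa": np.nan, "ecdf_x": np.array([]),
                "ecdf": lambda q: np.nan}
    xs = np.sort(amps)

    def ecdf(q):
        return np.searchsorted(xs, q, side="right") / n

    return {
        "n": int(n),
        "rate_hz": float(rate),
        "mean_amplitude_pa": float(amps.mean()),
        "sem_amplitude_pa": float(amps.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "ecdf_x": xs,
        "ecdf": ecdf,
    }


def detect_bursts(
    event_times: np.ndarray,
    max_isi_s: float = 0.1,
    min_events: int = 3,
    recording_duration_s: float | None = None,
) -> BurstSummary:
    """Segment event times into network bursts.

    A burst is a maximal run of ≥ ``min_events`` consecutive events with
    every inter-event interval ≤ ``max_isi_s``; its duration is the span
    from first to last event of the run.
    """
    t = np.asarray(event_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("event times must be sorted")
    duration = (recording_duration_s if recording_duration_s is not None
                else (float(t[-1]) if t.size else 0.0))
    intervals: list[tuple[float, float]] = []
    if t.size:
        isi = np.diff(t)
        linked = isi <= max_isi_s
        # runs of consecutive linked intervals
        i = 0
        while i < linked.size:
            if linked[i]:
                j = i
                while j < linked.size and linked[j]:
                    j += 1
                n_ev = j - i + 1
                if n_ev >= min_events:
                    intervals.append((float(t[i]), float(t[j])))
                i = j
            else:
                i += 1
    durations = np.array([e - s for s, e in intervals])
    ibis = np.array([intervals[k + 1][0] - intervals[k][1]
                     for k in range(len(intervals) - 1)])
    rate = len(intervals) / duration if duration > 0 else np.nan
    return BurstSummary(
        intervals=intervals,
        durations=durations,
        burst_rate_hz=float(rate) if duration > 0 else np.nan,
        interburst_intervals=ibis,
        recording_duration_s=float(duration),
    )
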