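"""Current-clamp analysis: spike detection, rheobase-spike shape, excitability.

A spike is an upward crossing of a dV/dt threshold whose voltage reaches a
minimum peak level within 5 ms; crossings closer than a refractory period
are merged.  Shape features are measured on the first spike of the
rheobase sweep (the lowest-amplitude step that evokes any spike) and are
threshold-referenced: amplitude = peak − threshold, FWHM at
threshold + amplitude/2, fast AHP = post-spike trough − threshold
(negative when a trough exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SweepSet, Trace

__all__ = [
    "SpikeShape",
    "ExcitabilitySummary",
    "detect_spikes",
    "first_spike_features",
    "excitability_summary",
]

DVDT_THRESH_DEFAULT = 10.0   # mV/ms
MIN_PEAK_DEFAULT = -10.0     # mV
REFRACTORY_MS_DEFAULT = 2.0
PEAK_SEARCH_MS = 5.0         # window after the dV/dt crossing for peak validation
FAHP_WINDOW_MS_DEFAULT = 20.0
MIN_FS = 2000.0


@dataclass
class SpikeShape:
    """Shape of the rheobase ("first") spike."""

    threshold_mv: float
    peak_mv: float
    amplitude_mv: float     # peak − threshold
    fwhm_ms: float
    fahp_mv: float          # trough − threshold; ≤ 0 when a trough exists
    peak_time_s: float
    rheobase_pa: float


@dataclass
class ExcitabilitySummary:
    """Step-protocol excitability counts (spikes inside the stimulus window)."""

    total_evoked: int
    max_per_step: int
    rheobase_pa: float | None   # None when no step evokes a spike
    per_step_counts: list[int]


DVDT_SMOOTH_MS = 0.5


def _dvdt(v: np.ndarray, fs: float) -> np.ndarray:
    """Time derivative in mV/ms, lightly smoothed against sample noise."""
    d = np.gradient(v) * fs / 1000.0
    w = max(1, int(round(DVDT_SMOOTH_MS / 1000.0 * fs)))
    if w > 1:
        d = np.convolve(d, np.ones(w) / w, mode="same")
    return d


def _spike_indices(
    v: np.ndarray,
    fs: float,
    dvdt_thresh: float,
    min_peak: float,
    refractory_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (crossing indices, peak indices) of validated spikes."""
    dvdt = _dvdt(v, fs)
    up = np.flatnonzero((dvdt[:-1] < dvdt_thresh) & (dvdt[1:] >= dvdt_thresh)) + 1
    look = int(round(PEAK_SEARCH_MS / 1000.0 * fs))
    refr = refractory_ms / 1000.0 * fs
    crossings, peaks = [], []
    last = -np.inf
    for c in up:
        if c - last < refr:
            continue
        win = v[c: c + look + 1]
        if win.size and win.max() >= min_peak:
            pk = c + int(np.argmax(win))
            if peaks and pk == peaks[-1]:
                continue  # same peak reached from a second noise crossing
            crossings.append(c)
            peaks.append(pk)
            last = c
    return np.asarray(crossings, dtype=np.int64), np.asarray(peaks, dtype=np.int64)


def detect_spikes(
    trace: Trace,
    dvdt_thresh: float = DVDT_THRESH_DEFAULT,
    min_peak: float = MIN_PEAK_DEFAULT,
    refractory_ms: float = REFRACTORY_MS_DEFAULT,
) -> np.ndarray:
    """Detect action potentials on a voltage trace.

    Returns spike peak times in seconds, ordered.  Raises on empty traces
    and on sampling rates too low to resolve the upstroke.
    """
    if trace.kind != "voltage":
        raise ValueError("spike detection requires a voltage trace")
    if trace.n == 0:
        raise ValueError("empty trace")
    if trace.fs < MIN_FS:
        raise ValueError(f"fs={trace.fs} Hz is below the {MIN_FS} Hz minimum")
    _, peaks = _spike_indices(trace.samples, trace.fs, dvdt_thresh, min_peak,
                              refractory_ms)
    return trace.t0 + peaks / trace.fs


def excitability_summary(
    sweepset: SweepSet,
    dvdt_thresh: float = DVDT_THRESH_DEFAULT,
    min_peak: float = MIN_PEAK_DEFAULT,
    refractory_ms: float = REFRACTORY_MS_DEFAULT,
) -> ExcitabilitySummary:
    """Count evoked spikes per step; spikes outside the step window are ignored."""
    proto = sweepset.protocol
    if proto.mode != "current_clamp_steps":
        raise ValueError("excitability summary requires a current-clamp step protocol")
    counts = []
    for tr in sweepset.traces:
        t = detect_spikes(tr, dvdt_thresh, min_peak, refractory_ms)
        counts.append(int(np.sum((t >= proto.step_onset) & (t < proto.step_offset))))
    rheo = None
    for amp, c in zip(proto.step_amplitudes, counts):
        if c >= 1:
            rheo = float(amp)
            break
    return ExcitabilitySummary(
        total_evoked=int(sum(counts)),
        max_per_step=int(max(counts)) if counts else 0,
        rheobase_pa=rheo,
        per_step_counts=counts,
    )


def first_spike_features(
    sweepset: SweepSet,
    dvdt_thresh: float = DVDT_THRESH_DEFAULT,
    min_peak: float = MIN_PEAK_DEFAULT,
    refractory_ms: float = REFRACTORY_MS_DEFAULT,
    fahp_window_ms: float = FAHP_WINDOW_MS_DEFAULT,
) -> SpikeShape:
    """Shape of the first spike on the rheobase sweep.

    Threshold is the voltage at the start of the contiguous dV/dt ≥ thresh
    run leading into the peak; FWHM is measured at threshold + amplitude/2
    with subsample interpolation at the two half-height crossings; the fast
    AHP is the minimum voltage within ``fahp_window_ms`` after V falls back
    below threshold, truncated at the next spike's crossing, minus
    threshold.

    Raises ``ValueError`` if no sweep contains a spike inside the step
    window.
    """
    proto = sweepset.protocol
    fs = sweepset.fs
    on = int(round(proto.step_onset * fs))
    off = int(round(proto.step_offset * fs))
    for amp, tr in zip(proto.step_amplitudes, sweepset.traces):
        v = tr.samples
        crossings, peaks = _spike_indices(v, fs, dvdt_thresh, min_peak,
                                          refractory_ms)
        in_step = (peaks >= on) & (peaks < off)
        if not np.any(in_step):
            continue
        crossings, peaks = crossings[in_step], peaks[in_step]
        c, pk = int(crossings[0]), int(peaks[0])

        dvdt = _dvdt(v, fs)
        # walk back from the crossing to the start of the suprathreshold run
        i = c
        while i > 0 and dvdt[i - 1] >= dvdt_thresh:
            i -= 1
        threshold = float(v[i])
        peak_v = float(v[pk])
        amplitude = peak_v - threshold
        if amplitude <= 0:
            continue
        half = threshold + amplitude / 2.0

        # half-height crossings around the peak, with linear interpolation
        li = pk
        while li > 0 and v[li - 1] >= half:
            li -= 1
        ri = pk
        while ri < v.size - 1 and v[ri + 1] >= half:
            ri += 1
        left = li - (v[li] - half) / (v[li] - v[li - 1]) if li > 0 and v[li - 1] < v[li] else li
        right = ri + (v[ri] - half) / (v[ri] - v[ri + 1]) if ri < v.size - 1 and v[ri + 1] < v[ri] else ri
        fwhm_ms = (right - left) * 1000.0 / fs

        # fAHP window: after V falls below threshold, up to the next spike;
        # undefined (NaN) when V plateaus above threshold until the next
        # spike or the end of the record — there is no trough to measure
        j = pk
        later = crossings[crossings > pk]
        j_stop = int(later[0]) if later.size else v.size - 1
        while j < j_stop and v[j] >= threshold:
            j += 1
        if v[j] >= threshold:
            fahp = np.nan
        else:
            j_end = j + int(round(fahp_window_ms / 1000.0 * fs))
            if later.size:
                j_end = min(j_end, int(later[0]))
            j_end = min(j_end, v.size)
            fahp = float(v[j:j_end].min() - threshold) if j_end > j else np.nan

        return SpikeShape(
            threshold_mv=threshold,
            peak_mv=peak_v,
            amplitude_mv=amplitude,
            fwhm_ms=float(fwhm_ms),
            fahp_mv=fahp,
            peak_time_s=tr.t0 + pk / fs,
            rheobase_pa=float(amp),
        )
    raise ValueError("no spikes in any sweep; shape features undefined")
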