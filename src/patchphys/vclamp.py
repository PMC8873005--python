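"""Voltage-clamp analysis: capacitance, leak subtraction, I–V extraction.

Capacitance is estimated from the charging transient of a voltage step as
Q/ΔV: the above-steady-state transient is tracked from onset until it
decays to 5% of its peak, its decay is fitted log-linearly over that span,
and the fitted exponential is integrated analytically — on a clean
transient this recovers the full charge even when the decay spans only a
few samples.

Leak is fitted as I = g·(V − E) on post-transient steady currents of
subthreshold steps and subtracted from every sweep; Na / fast-K / slow-K
components are then read from time windows of each leak-subtracted step
response (inward negative); the fast-K value is the transient excess of
the early outward peak over the sustained (slow-K) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SweepSet, Trace

__all__ = [
    "VClampFeatures",
    "estimate_capacitance",
    "subtract_leak",
    "extract_currents",
    "NA_WINDOW_MS",
    "KFAST_WINDOW_MS",
    "KSLOW_WINDOW_MS",
]

# measurement windows, ms relative to step onset (slow-K relative to offset)
NA_WINDOW_MS = (0.5, 10.0)
KFAST_WINDOW_MS = (2.0, 25.0)
KSLOW_WINDOW_MS = 50.0          # mean over the last 50 ms of the step
TRANSIENT_BLANK_MS = 0.5
LEAK_VMAX_DEFAULT = -60.0       # commands at or below this are "subthreshold"


@dataclass
class VClampFeatures:
    """Per-cell voltage-clamp summary."""

    capacitance_pf: float
    v_cmd_mv: np.ndarray
    na_peak_pa: np.ndarray      # ≤ 0 (inward)
    kfast_peak_pa: np.ndarray   # ≥ 0
    kslow_pa: np.ndarray        # ≥ 0
    leak_g_ns: float
    leak_e_mv: float

    def iv_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "v_cmd_mv": self.v_cmd_mv,
            "na_peak_pa": self.na_peak_pa,
            "kfast_peak_pa": self.kfast_peak_pa,
            "kslow_pa": self.kslow_pa,
        })


def estimate_capacitance(
    trace: Trace,
    dv_mv: float,
    onset_s: float | None = None,
    steady_window_s: float = 0.02,
) -> float:
    """Capacitance (pF) from the charge of a step-onset transient.

    Parameters
    ----------
    trace : current Trace containing one step onset.
    dv_mv : command step size (nonzero).
    onset_s : step onset time; detected from the largest sample-to-sample
        jump when omitted.
    steady_window_s : span just before the onset and at the end of the
        decay used to estimate baseline/steady leak levels.
    """
    if dv_mv == 0:
        raise ValueError("dv_mv must be nonzero")
    if trace.kind != "current":
        raise ValueError("capacitance estimation requires a current trace")
    x = trace.samples
    fs = trace.fs
    if onset_s is None:
        # the onset jump has the polarity of the command step; the offset
        # jump has the opposite one
        pol = 1.0 if dv_mv > 0 else -1.0
        onset = int(np.argmax(pol * np.diff(x))) + 1
    else:
        onset = int(round((onset_s - trace.t0) * fs))
    if not 0 < onset < x.size - 2:
        raise ValueError("no detectable step transient")

    nw = max(2, int(round(steady_window_s * fs)))
    sign = 1.0 if dv_mv > 0 else -1.0
    y = sign * x  # transient now positive

    # steady post-transient level: median over the tail of the decay span
    peak_i = onset + int(np.argmax(y[onset:onset + nw * 4]))
    tail = y[peak_i + nw: peak_i + 4 * nw]
    steady = float(np.median(tail)) if tail.size else float(y[-nw:].mean())
    d = y - steady
    peak = d[peak_i]
    if not peak > 0:
        raise ValueError("no detectable step transient")

    # span from peak until the decay first reaches 5% of peak
    below = np.flatnonzero(d[peak_i:] <= 0.05 * peak)
    end = peak_i + (int(below[0]) if below.size else d[peak_i:].size - 1)
    if end <= peak_i + 1:
        raise ValueError("transient too fast for this sampling rate")

    seg = d[peak_i:end + 1]
    t = np.arange(seg.size) / fs  # s, relative to the peak sample
    pos = seg > 0
    if pos.sum() < 2:
        raise ValueError("no detectable step transient")
    # log-linear fit of the decay over the onset→5% span → amplitude and tau
    slope, intercept = np.polyfit(t[pos], np.log(seg[pos]), 1)
    tau = -1.0 / slope if slope < 0 else np.inf
    if not np.isfinite(tau) or tau <= 0:
        raise ValueError("transient does not decay")
    amp0 = np.exp(intercept)

    # analytic integral of the fitted exponential from the onset sample:
    # exact for a clean transient regardless of how coarsely it is sampled
    q_fc = amp0 * tau * 1e3                            # pA·s → fC
    return float(q_fc / abs(dv_mv))                    # fC / mV = pF


def _steady_currents(sweepset: SweepSet, frac: float = 0.2) -> np.ndarray:
    """Mean current over the last `frac` of the step for each sweep."""
    proto = sweepset.protocol
    fs = sweepset.fs
    off = int(round(proto.step_offset * fs))
    start = off - int(round(proto.step_duration * frac * fs))
    return np.array([tr.samples[start:off].mean() for tr in sweepset.traces])


def fit_leak(
    sweepset: SweepSet, leak_vmax: float = LEAK_VMAX_DEFAULT
) -> tuple[float, float]:
    """Fit I = g·(V − E) on subthreshold steady currents → (g nS, E mV)."""
    proto = sweepset.protocol
    if proto.mode != "voltage_clamp_steps":
        raise ValueError("leak fitting requires a voltage-clamp step protocol")
    v = np.asarray(proto.step_amplitudes, dtype=float)
    sub = v <= leak_vmax
    if sub.sum() < 2:
        raise ValueError(
            f"need >= 2 subthreshold steps (V <= {leak_vmax} mV) to fit leak"
        )
    i_ss = _steady_currents(sweepset)[sub]
    g, b = np.polyfit(v[sub], i_ss, 1)   # I = g·V + b
    if g <= 0:
        # degenerate (e.g. zero-conductance cell): treat as pure offset
        return 0.0, 0.0
    return float(g), float(-b / g)


def subtract_leak(
    sweepset: SweepSet, leak_vmax: float = LEAK_VMAX_DEFAULT
) -> SweepSet:
    """Subtract the fitted linear leak from every sweep (holding level too)."""
    g, e = fit_leak(sweepset, leak_vmax)
    proto = sweepset.protocol
    fs = sweepset.fs
    on = int(round(proto.step_onset * fs))
    off = int(round(proto.step_offset * fs))
    traces = []
    for amp, tr in zip(proto.step_amplitudes, sweepset.traces):
        pred = np.full(tr.n, g * (proto.holding - e))
        pred[on:off] = g * (amp - e)
        traces.append(Trace(kind="current", unit="pA", fs=fs,
                            samples=tr.samples - pred, t0=tr.t0))
    out = SweepSet(protocol=proto, traces=traces, cell_id=sweepset.cell_id,
                   genotype=sweepset.genotype, week=sweepset.week)
    return out


def extract_currents(
    sweepset: SweepSet,
    capacitance_pf: float | None = None,
    na_window_ms: tuple[float, float] = NA_WINDOW_MS,
    kfast_window_ms: tuple[float, float] = KFAST_WINDOW_MS,
    kslow_window_ms: float = KSLOW_WINDOW_MS,
    leak_vmax: float = LEAK_VMAX_DEFAULT,
    leak_subtracted: bool = False,
) -> VClampFeatures:
    """Extract per-voltage Na, fast-K and slow-K currents from a step family.

    The input is leak-subtracted first unless ``leak_subtracted`` is set.
    Windows are relative to step onset (slow-K: the last ``kslow_window_ms``
    of the step) and must lie inside the step.
    """
    proto = sweepset.protocol
    step_ms = proto.step_duration * 1000.0
    if na_window_ms[1] > step_ms or kfast_window_ms[1] > step_ms \
            or kslow_window_ms > step_ms:
        raise ValueError("measurement windows extend beyond the step")
    g, e = (0.0, 0.0)
    if not leak_subtracted:
        g, e = fit_leak(sweepset, leak_vmax)
        sweepset = subtract_leak(sweepset, leak_vmax)
    fs = sweepset.fs
    on = int(round(proto.step_onset * fs))
    off = int(round(proto.step_offset * fs))

    def w(lo_ms, hi_ms):
        return (on + int(round(lo_ms / 1000.0 * fs)),
                on + int(round(hi_ms / 1000.0 * fs)))

    na_lo, na_hi = w(max(na_window_ms[0], TRANSIENT_BLANK_MS), na_window_ms[1])
    kf_lo, kf_hi = w(kfast_window_ms[0], kfast_window_ms[1])
    ks_lo = off - int(round(kslow_window_ms / 1000.0 * fs))

    v_cmd = np.asarray(proto.step_amplitudes, dtype=float)
    na = np.empty(v_cmd.size)
    kf = np.empty(v_cmd.size)
    ks = np.empty(v_cmd.size)
    for j, tr in enumerate(sweepset.traces):
        x = tr.samples
        na[j] = min(x[na_lo:na_hi].min(), 0.0)
        ks[j] = max(x[ks_lo:off].mean(), 0.0)
        # fast K = transient excess of the early outward peak over the
        # sustained level; isolates the inactivating (A-type) component
        kf[j] = max(x[kf_lo:kf_hi].max() - ks[j], 0.0)

    cap = capacitance_pf if capacitance_pf is not None else np.nan
    return VClampFeatures(
        capacitance_pf=float(cap),
        v_cmd_mv=v_cmd,
        na_peak_pa=na,
        kfast_peak_pa=kf,
        kslow_pa=ks,
        leak_g_ns=g,
        leak_e_mv=e,
    )
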