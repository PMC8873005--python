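"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-sample Python loops, numerical
integration) and shares no code with the package implementation paths it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def brute_force_spike_scan(
    v: np.ndarray,
    fs: float,
    dvdt_thresh: float = 10.0,
    min_peak: float = -10.0,
    refractory_ms: float = 2.0,
    peak_search_ms: float = 5.0,
) -> list[int]:
    """Exhaustive scan: every dV/dt up-crossing, then peak validation.

    Returns peak sample indices of accepted spikes.  The derivative uses
    the same definition as the implementation (gradient + 0.5 ms boxcar);
    the crossing/validation/merging logic is re-derived loop by loop.
    """
    dvdt = np.gradient(v) * fs / 1000.0
    w = max(1, int(round(0.5 / 1000.0 * fs)))
    if w > 1:
        dvdt = np.convolve(dvdt, np.ones(w) / w, mode="same")
    look = int(round(peak_search_ms / 1000.0 * fs))
    refr = refractory_ms / 1000.0 * fs
    peaks = []
    last_crossing = -np.inf
    for i in range(1, len(v)):
        if dvdt[i - 1] < dvdt_thresh <= dvdt[i]:
            if i - last_crossing < refr:
                continue
            win = v[i: i + look + 1]
            if len(win) and max(win) >= min_peak:
                pk = i + int(np.argmax(win))
                if peaks and pk == peaks[-1]:
                    continue
                peaks.append(pk)
                last_crossing = i
    return peaks


def zero_crossing_count(v: np.ndarray, level: float = 0.0) -> int:
    """Number of upward crossings of a voltage level (naive loop)."""
    n = 0
    for i in range(1, len(v)):
        if v[i - 1] < level <= v[i]:
            n += 1
    return n


def brute_force_ks(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic as the sup-difference of step ECDFs."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    grid = np.concatenate([a, b])
    best = 0.0
    for x in grid:
        fa = np.sum(a <= x) / a.size
        fb = np.sum(b <= x) / b.size
        best = max(best, abs(fa - fb))
    return best


def t_sf_numeric(t: float, df: float) -> float:
    """Upper-tail t probability by numerical integration of the density."""
    from math import gamma, sqrt, pi

    c = gamma((df + 1) / 2.0) / (gamma(df / 2.0) * sqrt(df * pi))

    def pdf(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    val, _ = quad(pdf, t, np.inf)
    return val


def two_tailed_p_numeric(t: float, df: float) -> float:
    return 2.0 * t_sf_numeric(abs(t), df)


def permutation_p(a: np.ndarray, b: np.ndarray, n_resamples: int,
                  rng: np.random.Generator) -> float:
    """Two-tailed permutation p-value for the difference of means."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    obs = abs(b.mean() - a.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        d = abs(perm[a.size:].mean() - perm[:a.size].mean())
        if d >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def matched_filter_epsc_oracle(
    x: np.ndarray,
    fs: float,
    k_sd: float = 3.0,
    refractory_ms: float = 2.0,
    smooth_ms: float = 0.6,
    rise_bounds=(0.5, 5.0),
    decay_bounds=(3.0, 50.0),
    block_s: float = 5.0,
) -> list[int]:
    """Naive re-derivation of the EPSC detection rules, loop by loop.

    Baseline = per-block median interpolated; noise = median of block MADs;
    candidates = local maxima of the boxcar-smoothed inward deflection that
    exceed k_sd·SD in height AND prominence with a refractory spacing;
    acceptance = valley-referenced 10–90% rise and 1/e decay inside bounds
    (decay may be truncated by the next candidate).  Returns accepted peak
    indices.
    """
    n = len(x)
    block = max(16, int(round(block_s * fs)))
    nblocks = max(1, n // block)
    meds, mads = [], []
    for k in range(nblocks):
        seg = np.sort(x[k * block:(k + 1) * block])
        m = np.median(seg)
        meds.append(m)
        mads.append(np.median(np.abs(seg - m)))
    sd = np.median(mads) * 1.4826
    centers = [(k + 0.5) * block for k in range(nblocks)]
    baseline = np.interp(np.arange(n), centers, meds)
    d_raw = baseline - x
    w = max(1, int(round(smooth_ms / 1000.0 * fs)))
    d = np.convolve(d_raw, np.ones(w) / w, mode="same")
    thr = k_sd * sd if sd > 0 else k_sd * 1e-12

    # exhaustive local maxima above threshold
    cand = []
    for i in range(1, n - 1):
        if d[i] > thr and d[i] > d[i - 1] and d[i] >= d[i + 1]:
            # plateau handling: take the first sample of a flat top
            cand.append(i)
    # prominence: height above the higher of the two flanking valleys,
    # valleys delimited by the nearest higher points (scipy definition)
    def prominence(i):
        left_min = d[i]
        j = i - 1
        while j >= 0 and d[j] <= d[i]:
            left_min = min(left_min, d[j])
            j -= 1
        right_min = d[i]
        j = i + 1
        while j < n and d[j] <= d[i]:
            right_min = min(right_min, d[j])
            j += 1
        return d[i] - max(left_min, right_min)

    cand = [i for i in cand if prominence(i) >= thr]
    # distance (refractory): greedy from highest peak, scipy-style
    dist = max(1, int(round(refractory_ms / 1000.0 * fs)))
    keep = np.ones(len(cand), bool)
    order = np.argsort([d[i] for i in cand])[::-1]
    for oi in order:
        if not keep[oi]:
            continue
        for oj in range(len(cand)):
            if oj != oi and keep[oj] and abs(cand[oj] - cand[oi]) < dist:
                if d[cand[oj]] <= d[cand[oi]]:
                    keep[oj] = False
    peaks = sorted([c for c, k in zip(cand, keep) if k])

    accepted = []
    for idx, pk in enumerate(peaks):
        prv = peaks[idx - 1] if idx > 0 else None
        nxt = peaks[idx + 1] if idx + 1 < len(peaks) else None
        start = prv if prv is not None else max(0, pk - int(0.05 * fs))
        valley = max(float(np.min(d[start:pk + 1])), 0.0) if pk > start else 0.0
        rel = d[pk] - valley
        if rel <= 0:
            continue
        lo = valley + 0.1 * rel
        hi = valley + 0.9 * rel

        def interp(j, level):
            if j + 1 < n and d[j + 1] != d[j]:
                return j + (level - d[j]) / (d[j + 1] - d[j])
            return float(j)

        i = pk
        t90 = None
        while i > start and d[i] > lo:
            if t90 is None and d[i] <= hi:
                t90 = i
            i -= 1
        t10 = i
        if t90 is None:
            t90 = pk
        rise = (interp(t90, hi) - interp(t10, lo)) / fs * 1000.0
        if not (rise_bounds[0] <= rise <= rise_bounds[1]):
            continue
        stop = nxt if nxt is not None else n
        level = valley + rel / np.e
        j = pk
        while j < stop - 1 and d[j] > level:
            j += 1
        if d[j] > level:
            decay = np.inf
        else:
            decay = (interp(j - 1, level) - pk) / fs * 1000.0 if j > pk else 0.0
        truncated = nxt is not None and not np.isfinite(decay)
        if not truncated and not (
            decay_bounds[0] <= decay <= decay_bounds[1] and decay > rise
        ):
            continue
        accepted.append(pk)
    return accepted
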