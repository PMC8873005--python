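"""Numba kernels for the single-compartment conductance model.

The model has four currents: transient Na (m³h), delayed-rectifier K (n⁴),
A-type fast K (a³b), and ohmic leak.  Na/Kd rate functions are the classic
alpha/beta forms with a voltage shift ``vt``; the A-type gates use
Boltzmann steady states with fixed time constants.  Gates and voltage are
advanced with exponential Euler at a fixed step (default 0.025 ms), which
is stable for these kinetics at the output rates used here.

Everything in this module works in mV / pA / nS / pF / ms so the membrane
equation carries no conversion factors.
"""

import math

import numpy as np
from numba import njit

__all__ = ["steady_gates", "run_current_clamp", "run_gates_clamped"]


@njit(cache=True, fastmath=True)
def _exprel(x, k):
    """x / (exp(x/k) - 1), with the removable singularity at x=0 filled."""
    if abs(x) < 1e-7:
        return k
    return x / (math.exp(x / k) - 1.0)


@njit(cache=True, fastmath=True)
def _rates_na_kd(v, vt, rate_scale):
    u = v - vt
    am = 0.32 * _exprel(13.0 - u, 4.0)
    bm = 0.28 * _exprel(u - 40.0, 5.0)
    ah = 0.128 * math.exp((17.0 - u) / 18.0)
    bh = 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
    an = 0.032 * _exprel(15.0 - u, 5.0)
    bn = 0.5 * math.exp((10.0 - u) / 40.0)
    s = rate_scale
    return am * s, bm * s, ah * s, bh * s, an * s, bn * s


@njit(cache=True, fastmath=True)
def _a_type_inf(v, a_vhalf, a_slope, b_vhalf, b_slope):
    a_inf = 1.0 / (1.0 + math.exp(-(v - a_vhalf) / a_slope))
    b_inf = 1.0 / (1.0 + math.exp((v - b_vhalf) / b_slope))
    return a_inf, b_inf


@njit(cache=True, fastmath=True)
def steady_gates(v, vt, a_vhalf, a_slope, b_vhalf, b_slope):
    """Gate steady-state values (m, h, n, a, b) at a fixed voltage."""
    am, bm, ah, bh, an, bn = _rates_na_kd(v, vt, 1.0)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
    a_inf, b_inf = _a_type_inf(v, a_vhalf, a_slope, b_vhalf, b_slope)
    return m, h, n, a_inf, b_inf


@njit(cache=True, fastmath=True)
def run_current_clamp(
    i_cmd,            # pA, one value per output sample (held for `stride` substeps)
    state,            # float64[6]: V, m, h, n, a, b — updated in place
    dt,               # ms, inner integration step
    stride,           # substeps per output sample
    c_m, g_na, g_kd, g_a, g_l,
    e_na, e_k, e_l,
    vt, rate_scale, a_vhalf, a_slope, a_tau, b_vhalf, b_slope, b_tau,
):
    """Integrate the membrane equation under injected current.

    Returns the voltage at each output sample (value after the substeps of
    that sample).  ``state`` carries (V, gates) across calls so a settling
    run and the recorded sweep compose exactly.
    """
    n_out = i_cmd.shape[0]
    out = np.empty(n_out)
    v = state[0]
    m = state[1]
    h = state[2]
    n = state[3]
    a = state[4]
    b = state[5]
    ea_fac = 1.0 - math.exp(-dt / a_tau)
    eb_fac = 1.0 - math.exp(-dt / b_tau)
    for j in range(n_out):
        i_inj = i_cmd[j]
        for _ in range(stride):
            am, bm, ah, bh, an, bn = _rates_na_kd(v, vt, rate_scale)
            m += (am / (am + bm) - m) * (1.0 - math.exp(-dt * (am + bm)))
            h += (ah / (ah + bh) - h) * (1.0 - math.exp(-dt * (ah + bh)))
            n += (an / (an + bn) - n) * (1.0 - math.exp(-dt * (an + bn)))
            a_inf, b_inf = _a_type_inf(v, a_vhalf, a_slope, b_vhalf, b_slope)
            a += (a_inf - a) * ea_fac
            b += (b_inf - b) * eb_fac
            g_na_eff = g_na * m * m * m * h
            g_kd_eff = g_kd * n * n * n * n
            g_a_eff = g_a * a * a * a * b
            g_tot = g_na_eff + g_kd_eff + g_a_eff + g_l
            v_inf = (
                g_na_eff * e_na + (g_kd_eff + g_a_eff) * e_k + g_l * e_l + i_inj
            ) / g_tot
            v += (v_inf - v) * (1.0 - math.exp(-dt * g_tot / c_m))
        out[j] = v
    state[0] = v
    state[1] = m
    state[2] = h
    state[3] = n
    state[4] = a
    state[5] = b
    return out


@njit(cache=True, fastmath=True)
def run_gates_clamped(
    v_cmd,            # mV, one value per output sample
    state,            # float64[6] as above; state[0] tracks the command
    dt, stride,
    g_na, g_kd, g_a, g_l,
    e_na, e_k, e_l,
    vt, rate_scale, a_vhalf, a_slope, a_tau, b_vhalf, b_slope, b_tau,
):
    """Integrate the gating ODEs at the commanded potential.

    Returns the total ionic current (pA, inward negative) at each output
    sample.  The capacitive transient is not included here; it is added
    analytically by the caller.
    """
    n_out = v_cmd.shape[0]
    out = np.empty(n_out)
    m = state[1]
    h = state[2]
    n = state[3]
    a = state[4]
    b = state[5]
    ea_fac = 1.0 - math.exp(-dt / a_tau)
    eb_fac = 1.0 - math.exp(-dt / b_tau)
    for j in range(n_out):
        v = v_cmd[j]
        for _ in range(stride):
            am, bm, ah, bh, an, bn = _rates_na_kd(v, vt, rate_scale)
            m += (am / (am + bm) - m) * (1.0 - math.exp(-dt * (am + bm)))
            h += (ah / (ah + bh) - h) * (1.0 - math.exp(-dt * (ah + bh)))
            n += (an / (an + bn) - n) * (1.0 - math.exp(-dt * (an + bn)))
            a_inf, b_inf = _a_type_inf(v, a_vhalf, a_slope, b_vhalf, b_slope)
            a += (a_inf - a) * ea_fac
            b += (b_inf - b) * eb_fac
        out[j] = (
            g_na * m * m * m * h * (v - e_na)
            + (g_kd * n * n * n * n + g_a * a * a * a * b) * (v - e_k)
            + g_l * (v - e_l)
        )
    state[0] = v_cmd[n_out - 1]
    state[1] = m
    state[2] = h
    state[3] = n
    state[4] = a
    state[5] = b
    return out
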