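"""Synthetic patch-clamp recordings from a single-compartment conductance model.

Three recording modes are generated:

* current clamp — step-current families integrated through the full
  membrane equation ``C_m dV/dt = −I_Na − I_Kd − I_A − I_L + I_inj + ξ``;
* voltage clamp — gating ODEs integrated at the commanded potential, with
  an analytic series-resistance capacitive transient (charge ``C_m·ΔV``,
  decay ``R_s·C_m``) added at each step edge;
* gap-free synaptic — doubly stochastic Poisson trains of biexponential
  inward EPSC kernels on a noisy baseline, returned together with the
  ground-truth event table.

``generate_cohort`` draws labelled control/mutant cells across maturation
weeks from per-condition parameter distributions; a single master seed
fully determines every recording.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _hh
from .types import (
    CohortSpec,
    ConditionSpec,
    GatingKinetics,
    NeuronParams,
    ProtocolSpec,
    SweepSet,
    SynapticInputStats,
    Trace,
)

__all__ = [
    "DT_MS",
    "SETTLE_MS",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_synaptic_recording",
    "SynapticTruth",
    "CellRecording",
    "Cohort",
    "generate_cohort",
    "default_cohort_spec",
    "default_cc_protocol",
    "default_vc_protocol",
]

DT_MS = 0.025     # inner integration step, ms
SETTLE_MS = 200.0  # settling run before each sweep (not recorded)


def _check_params(params: NeuronParams) -> None:
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if isinstance(v, (int, float)) and not np.isfinite(v):
            raise ValueError(f"non-finite parameter {f.name}={v}")


def _kin_args(k: GatingKinetics) -> tuple:
    return (k.vt, k.rate_scale, k.a_vhalf, k.a_slope, k.a_tau_ms,
            k.b_vhalf, k.b_slope, k.b_tau_ms)


def _stride(fs: float) -> int:
    sample_ms = 1000.0 / fs
    stride = int(round(sample_ms / DT_MS))
    if stride < 1 or abs(stride * DT_MS - sample_ms) > 1e-9:
        raise ValueError(f"fs={fs} is not an integer multiple of the {DT_MS} ms step")
    return stride


def _initial_state(params: NeuronParams, v0: float) -> np.ndarray:
    k = params.kinetics
    m, h, n, a, b = _hh.steady_gates(
        v0, k.vt, k.a_vhalf, k.a_slope, k.b_vhalf, k.b_slope
    )
    return np.array([v0, m, h, n, a, b])


def simulate_current_clamp(
    params: NeuronParams,
    protocol: ProtocolSpec,
    seed: int,
    fs: float = 10_000.0,
) -> SweepSet:
    """Simulate a current-clamp step family; one voltage trace per step."""
    if protocol.mode != "current_clamp_steps":
        raise ValueError(f"expected current_clamp_steps protocol, got {protocol.mode}")
    _check_params(params)
    stride = _stride(fs)
    kin = _kin_args(params.kinetics)
    n_out = int(round(protocol.sweep_duration * fs))
    n_settle = int(round(SETTLE_MS / 1000.0 * fs))
    on = int(round(protocol.step_onset * fs))
    off = int(round(protocol.step_offset * fs))
    rng = np.random.default_rng(seed)
    cell_args = (params.c_m, params.g_na, params.g_kd, params.g_a, params.g_l,
                 params.e_na, params.e_k, params.e_l)
    # the settling run is noise-free and identical for every sweep
    state0 = _initial_state(params, params.e_l)
    _hh.run_current_clamp(
        np.full(n_settle, float(protocol.holding)), state0, DT_MS, stride,
        *cell_args, *kin,
    )
    traces = []
    for amp in protocol.step_amplitudes:
        i_cmd = np.full(n_out, float(protocol.holding))
        i_cmd[on:off] = amp
        if params.noise_sd > 0:
            i_cmd = i_cmd + rng.normal(0.0, params.noise_sd, size=n_out)
        state = state0.copy()
        v = _hh.run_current_clamp(i_cmd, state, DT_MS, stride, *cell_args, *kin)
        traces.append(Trace(kind="voltage", unit="mV", fs=fs, samples=v))
    return SweepSet(protocol=protocol, traces=traces)


def simulate_voltage_clamp(
    params: NeuronParams,
    protocol: ProtocolSpec,
    seed: int,
    fs: float = 10_000.0,
    transient: bool = True,
) -> SweepSet:
    """Simulate a voltage-clamp step family; one current trace per command step.

    Sign convention: inward current is negative.  Each step edge carries an
    analytic capacitive transient of total charge ``C_m·ΔV`` decaying with
    ``τ = R_s·C_m``.
    """
    if protocol.mode != "voltage_clamp_steps":
        raise ValueError(f"expected voltage_clamp_steps protocol, got {protocol.mode}")
    _check_params(params)
    if transient and params.r_s <= 0:
        raise ValueError("r_s must be > 0 when the capacitive transient is simulated")
    stride = _stride(fs)
    kin = _kin_args(params.kinetics)
    n_out = int(round(protocol.sweep_duration * fs))
    n_settle = int(round(SETTLE_MS / 1000.0 * fs))
    on = int(round(protocol.step_onset * fs))
    off = int(round(protocol.step_offset * fs))
    rng = np.random.default_rng(seed)
    chan_args = (params.g_na, params.g_kd, params.g_a, params.g_l,
                 params.e_na, params.e_k, params.e_l)
    t_ms = np.arange(n_out) * (1000.0 / fs)
    tau_ms = params.r_s * params.c_m / 1000.0  # MΩ·pF = µs
    state0 = _initial_state(params, protocol.holding)
    _hh.run_gates_clamped(
        np.full(n_settle, float(protocol.holding)), state0, DT_MS, stride,
        *chan_args, *kin,
    )
    traces = []
    for amp in protocol.step_amplitudes:
        v_cmd = np.full(n_out, float(protocol.holding))
        v_cmd[on:off] = amp
        state = state0.copy()
        i = _hh.run_gates_clamped(v_cmd, state, DT_MS, stride, *chan_args, *kin)
        if transient:
            dv = amp - protocol.holding
            for edge, sign in ((on, 1.0), (off, -1.0)):
                tt = t_ms[edge:] - t_ms[edge]
                # mV / MΩ = nA → ×1000 pA
                i[edge:] += sign * (dv / params.r_s) * 1000.0 * np.exp(-tt / tau_ms)
        if params.noise_sd > 0:
            i = i + rng.normal(0.0, params.noise_sd, size=n_out)
        traces.append(Trace(kind="current", unit="pA", fs=fs, samples=i))
    return SweepSet(protocol=protocol, traces=traces)


def _epsc_kernel(tau_rise_ms: float, tau_decay_ms: float, fs: float) -> np.ndarray:
    """Unit-amplitude biexponential kernel sampled at fs (positive, peak 1)."""
    dt_ms = 1000.0 / fs
    t = np.arange(0.0, 8.0 * tau_decay_ms, dt_ms)
    k = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    tp = (tau_rise_ms * tau_decay_ms / (tau_decay_ms - tau_rise_ms)
          * np.log(tau_decay_ms / tau_rise_ms))
    peak = np.exp(-tp / tau_decay_ms) - np.exp(-tp / tau_rise_ms)
    return k / peak


@dataclass
class SynapticTruth:
    """Ground truth for one simulated gap-free recording."""

    events: pd.DataFrame   # time_s, amplitude_pa, in_burst
    epochs: pd.DataFrame   # start_s, duration_s

    @property
    def rate_hz(self) -> float:
        return float(self.events.attrs.get("rate_hz", np.nan))


def simulate_synaptic_recording(
    event_stats: SynapticInputStats,
    duration_s: float,
    fs: float,
    noise_sd: float,
    seed: int,
    baseline_pa: float = 0.0,
) -> tuple[Trace, SynapticTruth]:
    """Simulate a gap-free voltage-clamp current trace of spontaneous EPSCs.

    Event times follow a doubly stochastic Poisson process (sparse base
    rate plus burst epochs at a high within-burst rate); amplitudes are
    log-normal with the requested mean; each event contributes an inward
    biexponential kernel peak-normalised to −amplitude.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    s = event_stats
    if s.tau_rise_ms >= s.tau_decay_ms:
        raise ValueError("tau_rise must be < tau_decay")
    if fs * s.tau_rise_ms / 1000.0 < 5:
        raise ValueError(
            f"fs={fs} Hz cannot resolve tau_rise={s.tau_rise_ms} ms (need fs·τ_rise ≥ 5)"
        )
    rng = np.random.default_rng(seed)

    n_base = rng.poisson(s.base_rate_hz * duration_s)
    base_times = np.sort(rng.uniform(0.0, duration_s, size=n_base))

    n_epochs = rng.poisson(s.burst_rate_hz * duration_s)
    starts = np.sort(rng.uniform(0.0, duration_s, size=n_epochs))
    # gamma-shaped durations avoid near-zero epochs
    durs = rng.gamma(4.0, s.burst_duration_mean_s / 4.0, size=n_epochs)
    burst_times = []
    for st, du in zip(starts, durs):
        k = rng.poisson(s.within_burst_rate_hz * du)
        burst_times.append(st + np.sort(rng.uniform(0.0, du, size=k)))
    burst_times = (np.concatenate(burst_times) if burst_times
                   else np.empty(0))
    burst_times = burst_times[burst_times < duration_s]

    times = np.concatenate([base_times, burst_times])
    in_burst = np.concatenate(
        [np.zeros(base_times.size, bool), np.ones(burst_times.size, bool)]
    )
    order = np.argsort(times, kind="stable")
    times, in_burst = times[order], in_burst[order]

    if s.amp_mean_pa <= 0:
        amps = np.zeros(times.size)
    else:
        mu = np.log(s.amp_mean_pa) - 0.5 * s.amp_sigma_ln**2
        amps = rng.lognormal(mu, s.amp_sigma_ln, size=times.size)

    n = int(round(duration_s * fs))
    impulses = np.zeros(n)
    idx = np.minimum((times * fs).astype(np.int64), n - 1)
    np.add.at(impulses, idx, amps)
    kernel = _epsc_kernel(s.tau_rise_ms, s.tau_decay_ms, fs)
    x = baseline_pa - np.convolve(impulses, kernel)[:n]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)

    events = pd.DataFrame(
        {"time_s": times, "amplitude_pa": amps, "in_burst": in_burst}
    )
    events.attrs["rate_hz"] = times.size / duration_s
    epochs = pd.DataFrame({"start_s": starts, "duration_s": durs})
    trace = Trace(kind="current", unit="pA", fs=fs, samples=x)
    return trace, SynapticTruth(events=events, epochs=epochs)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CellRecording:
    """All synthetic recordings for one cell."""

    cell_id: str
    genotype: str
    week: int
    params: NeuronParams
    synaptic: SynapticInputStats
    cc: SweepSet
    vc: SweepSet
    syn_trace: Trace
    syn_truth: SynapticTruth


@dataclass
class Cohort:
    cells: list[CellRecording]
    truth: pd.DataFrame
    spec: CohortSpec


def default_cc_protocol() -> ProtocolSpec:
    """Current steps −10…+60 pA in 5 pA increments, 400 ms, from 0 pA holding."""
    return ProtocolSpec(
        mode="current_clamp_steps",
        holding=0.0,
        step_amplitudes=list(np.arange(-10.0, 60.0 + 1e-9, 5.0)),
        step_onset=0.1,
        step_offset=0.5,
        sweep_duration=0.6,
    )


def default_vc_protocol() -> ProtocolSpec:
    """Voltage steps −90…+40 mV in 10 mV increments from −70 mV holding, 200 ms."""
    return ProtocolSpec(
        mode="voltage_clamp_steps",
        holding=-70.0,
        step_amplitudes=list(np.arange(-90.0, 40.0 + 1e-9, 10.0)),
        step_onset=0.1,
        step_offset=0.3,
        sweep_duration=0.4,
    )


_PARAM_DRAW_FIELDS = ("c_m", "g_na", "g_kd", "g_a", "g_l")
_SYN_DRAW_FIELDS = ("base_rate_hz", "amp_mean_pa", "burst_rate_hz")


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _draw_cell(
    cond: ConditionSpec, rng: np.random.Generator, noise_sd: float
) -> tuple[NeuronParams, SynapticInputStats]:
    kw = {}
    for f in _PARAM_DRAW_FIELDS:
        cv = cond.params_cv.get(f, 0.0)
        kw[f] = getattr(cond.params_mean, f) * _lognormal_multiplier(rng, cv)
    params = cond.params_mean.with_(noise_sd=noise_sd, **kw)
    skw = {}
    for f in _SYN_DRAW_FIELDS:
        cv = cond.params_cv.get("syn_" + f, cond.params_cv.get("syn", 0.0))
        skw[f] = getattr(cond.synaptic, f) * _lognormal_multiplier(rng, cv)
    synaptic = dataclasses.replace(cond.synaptic, **skw)
    return params, synaptic


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw and simulate a labelled cohort; master seed determines everything.

    Per-cell seeds are spawned from ``SeedSequence(master_seed)`` in a fixed
    order (condition-major, cell-minor, then draw/cc/vc/syn within a cell),
    so identical specs yield identical cohorts.
    """
    if not spec.conditions:
        raise ValueError("cohort spec has no conditions")
    cc_proto = spec.cc_protocol or default_cc_protocol()
    vc_proto = spec.vc_protocol or default_vc_protocol()
    ss = np.random.SeedSequence(spec.master_seed)
    cells: list[CellRecording] = []
    rows = []
    for cond in spec.conditions:
        for i in range(spec.n_per_condition):
            cell_id = f"{cond.genotype}_w{cond.week}_c{i:03d}"
            draw_ss, cc_ss, vc_ss, syn_ss = ss.spawn(4)
            rng = np.random.default_rng(draw_ss)
            params, synaptic = _draw_cell(cond, rng, spec.noise_sd_pa)
            cc_seed = int(cc_ss.generate_state(1)[0] % (2**31))
            vc_seed = int(vc_ss.generate_state(1)[0] % (2**31))
            syn_seed = int(syn_ss.generate_state(1)[0] % (2**31))
            cc = simulate_current_clamp(params, cc_proto, cc_seed)
            vc = simulate_voltage_clamp(params, vc_proto, vc_seed)
            syn_trace, syn_truth = simulate_synaptic_recording(
                synaptic, spec.gapfree_duration_s, spec.gapfree_fs,
                spec.noise_sd_pa, syn_seed,
            )
            for sw in (cc, vc):
                sw.cell_id = cell_id
                sw.genotype = cond.genotype
                sw.week = cond.week
            cells.append(CellRecording(
                cell_id=cell_id, genotype=cond.genotype, week=cond.week,
                params=params, synaptic=synaptic,
                cc=cc, vc=vc, syn_trace=syn_trace, syn_truth=syn_truth,
            ))
            row = {
                "cell_id": cell_id,
                "genotype": cond.genotype,
                "week": cond.week,
            }
            for f in ("c_m", "g_na", "g_kd", "g_a", "g_l", "e_na", "e_k",
                      "e_l", "r_s", "noise_sd"):
                row[f] = getattr(params, f)
            for f in ("base_rate_hz", "amp_mean_pa", "amp_sigma_ln",
                      "burst_rate_hz", "within_burst_rate_hz",
                      "burst_duration_mean_s"):
                row["syn_" + f] = getattr(synaptic, f)
            # mean event rate implied by the generator inputs
            row["syn_total_rate_hz"] = (
                synaptic.base_rate_hz
                + synaptic.burst_rate_hz * synaptic.burst_duration_mean_s
                * synaptic.within_burst_rate_hz
            )
            row["syn_true_event_rate_hz"] = syn_truth.rate_hz
            rows.append(row)
    return Cohort(cells=cells, truth=pd.DataFrame(rows), spec=spec)


def default_cohort_spec(master_seed: int = 0, n_per_condition: int = 20) -> CohortSpec:
    """The default maturation cohort: control vs mutant at weeks 5, 7, 11.

    The preset encodes the phenotype axes the pipeline is designed to
    resolve: at weeks 5 and 7 the mutant condition carries larger Na,
    delayed-rectifier and A-type conductances than control (hyperexcitable,
    deeper fast AHP, narrower spikes); by week 11 the ordering reverses for
    Na/Kd (hypoexcitable) and the mutant synaptic drive collapses (event
    rate ≤ 0.25× control, burst-epoch rate ≤ 0.2× with ≥ 6× interburst
    spacing, shorter bursts).  Capacitance grows with maturation and does
    not differ by genotype.  The numeric values are implementation
    defaults calibrated on the model, not measurements.
    """
    cv = {"c_m": 0.15, "g_na": 0.18, "g_kd": 0.18, "g_a": 0.18, "g_l": 0.15,
          "syn_base_rate_hz": 0.3, "syn_amp_mean_pa": 0.15}

    def cond(genotype, week, c_m, g_l, g_na, g_kd, g_a, syn):
        return ConditionSpec(
            genotype=genotype, week=week,
            params_mean=NeuronParams(c_m=c_m, g_l=g_l, g_na=g_na,
                                     g_kd=g_kd, g_a=g_a),
            params_cv=dict(cv),
            synaptic=syn,
        )

    quiet5 = dict(burst_rate_hz=0.0, tau_rise_ms=2.0, tau_decay_ms=10.0)
    conditions = [
        cond("control", 5, 25.0, 1.0, 50.0, 9.0, 8.0,
             SynapticInputStats(base_rate_hz=0.10, amp_mean_pa=20.0, **quiet5)),
        cond("mutant", 5, 25.0, 1.0, 80.0, 14.0, 22.0,
             SynapticInputStats(base_rate_hz=0.12, amp_mean_pa=30.0, **quiet5)),
        cond("control", 7, 28.0, 1.2, 80.0, 12.0, 8.0,
             SynapticInputStats(base_rate_hz=0.25, amp_mean_pa=25.0, **quiet5)),
        cond("mutant", 7, 28.0, 1.2, 92.0, 17.0, 36.0,
             SynapticInputStats(base_rate_hz=0.25, amp_mean_pa=27.0, **quiet5)),
        cond("control", 11, 52.0, 2.0, 190.0, 32.0, 25.0,
             SynapticInputStats(base_rate_hz=1.0, amp_mean_pa=30.0,
                                burst_rate_hz=0.05, within_burst_rate_hz=60.0,
                                burst_duration_mean_s=1.5)),
        cond("mutant", 11, 52.0, 2.0, 140.0, 24.0, 20.0,
             SynapticInputStats(base_rate_hz=0.25, amp_mean_pa=30.0,
                                burst_rate_hz=0.008, within_burst_rate_hz=60.0,
                                burst_duration_mean_s=0.6)),
    ]
    return CohortSpec(
        conditions=conditions,
        n_per_condition=n_per_condition,
        master_seed=master_seed,
    )
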