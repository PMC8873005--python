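"""Core containers for patch-clamp data and simulation parameters.

Unit conventions used throughout the package: time in seconds at the API
surface (sampling rates in Hz), voltages in mV, currents in pA,
capacitance in pF, conductance in nS, series resistance in MΩ.  With this
system ``pF·mV/ms = pA`` and ``nS·mV = pA``, so the membrane equation needs
no unit conversion factors when integrated in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Trace",
    "ProtocolSpec",
    "SweepSet",
    "GatingKinetics",
    "NeuronParams",
    "SynapticInputStats",
    "ConditionSpec",
    "CohortSpec",
]


@dataclass
class Trace:
    """One uniformly sampled recording channel.

    Parameters
    ----------
    kind : {"voltage", "current"}
        Physical quantity carried by the trace.
    unit : {"mV", "pA"}
        Must be consistent with ``kind`` (voltage → mV, current → pA).
    fs : float
        Sampling rate in Hz.
    samples : ndarray
        Ordered sample values.
    t0 : float
        Time of the first sample in seconds.
    """

    kind: Literal["voltage", "current"]
    unit: Literal["mV", "pA"]
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.kind == "voltage" and self.unit != "mV":
            raise ValueError("voltage traces must be in mV")
        if self.kind == "current" and self.unit != "pA":
            raise ValueError("current traces must be in pA")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples at 1/fs spacing)."""
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class ProtocolSpec:
    """Stimulus description for one sweep family.

    ``mode`` selects the clamp configuration; amplitudes are absolute
    command levels during the step (pA for current clamp, mV for voltage
    clamp).  ``holding`` applies outside the step window.  All times are
    in seconds.
    """

    mode: Literal["current_clamp_steps", "voltage_clamp_steps", "gap_free"]
    holding: float = 0.0
    step_amplitudes: Sequence[float] = field(default_factory=list)
    step_onset: float = 0.1
    step_offset: float = 0.5
    sweep_duration: float = 0.6

    def __post_init__(self) -> None:
        if self.mode in ("current_clamp_steps", "voltage_clamp_steps"):
            if len(self.step_amplitudes) == 0:
                raise ValueError("step modes require a non-empty amplitude list")
            if not (0 <= self.step_onset < self.step_offset < self.sweep_duration):
                raise ValueError(
                    "require 0 <= onset < offset < duration, got "
                    f"{self.step_onset}, {self.step_offset}, {self.sweep_duration}"
                )

    @property
    def step_duration(self) -> float:
        return self.step_offset - self.step_onset


@dataclass
class SweepSet:
    """Ordered family of traces recorded under one protocol from one cell."""

    protocol: ProtocolSpec
    traces: list[Trace]
    cell_id: str = ""
    genotype: str = ""
    week: int | None = None

    def __post_init__(self) -> None:
        if self.protocol.mode != "gap_free":
            if len(self.traces) != len(self.protocol.step_amplitudes):
                raise ValueError(
                    f"{len(self.traces)} traces for "
                    f"{len(self.protocol.step_amplitudes)} step amplitudes"
                )
        if self.traces:
            fs0 = self.traces[0].fs
            n0 = self.traces[0].n
            for tr in self.traces:
                if tr.fs != fs0 or tr.n != n0:
                    raise ValueError("all traces in a SweepSet must share fs and length")

    @property
    def fs(self) -> float:
        return self.traces[0].fs

    @property
    def condition(self) -> str:
        return f"{self.genotype}_w{self.week}"


@dataclass(frozen=True)
class GatingKinetics:
    """Rate-function constants for the voltage-gated channels.

    The Na and delayed-rectifier rates follow the classic thermodynamic
    alpha/beta forms shifted by ``vt`` (mV); raising ``vt`` raises the spike
    threshold.  The A-type (fast, Kv1-like) conductance uses Boltzmann
    steady states with fixed time constants: activation ``a`` (gate cubed)
    is fast, inactivation ``b`` is slow, so the channel passes a transient
    outward current during and just after the spike, speeding
    repolarization and deepening the fast afterhyperpolarization.
    """

    vt: float = -55.0            # mV, threshold shift of Na/Kd rate functions
    rate_scale: float = 0.8      # multiplies all Na/Kd rates; <1 slows the spike
    a_vhalf: float = -35.0       # mV, A-type activation midpoint
    a_slope: float = 9.0         # mV
    a_tau_ms: float = 1.0
    b_vhalf: float = -62.0       # mV, A-type inactivation midpoint
    b_slope: float = 7.0         # mV
    b_tau_ms: float = 25.0


@dataclass(frozen=True)
class NeuronParams:
    """Single-compartment conductance-model parameters (generative ground truth)."""

    c_m: float = 30.0            # pF
    g_na: float = 80.0           # nS
    g_kd: float = 12.0           # nS
    g_a: float = 15.0            # nS, A-type / fast K (Kv1.5-like)
    g_l: float = 1.5             # nS
    e_na: float = 60.0           # mV
    e_k: float = -90.0           # mV
    e_l: float = -65.0           # mV
    r_s: float = 10.0            # MΩ, series resistance (voltage clamp only)
    noise_sd: float = 0.0        # pA, additive Gaussian current noise
    kinetics: GatingKinetics = field(default_factory=GatingKinetics)

    def __post_init__(self) -> None:
        for name in ("g_na", "g_kd", "g_a", "g_l", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.c_m) or self.c_m <= 0:
            raise ValueError(f"c_m must be finite and > 0, got {self.c_m}")
        if not (self.e_k < self.e_l < 0 < self.e_na):
            raise ValueError(
                f"require E_K < E_L < 0 < E_Na, got {self.e_k}, {self.e_l}, {self.e_na}"
            )

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SynapticInputStats:
    """Statistics of the spontaneous synaptic drive onto one cell.

    Event times follow a doubly stochastic Poisson process: a sparse base
    rate everywhere plus burst epochs (Poisson arrivals, gamma-distributed
    durations) during which the rate jumps to ``within_burst_rate_hz``.
    Amplitudes are log-normal.
    """

    base_rate_hz: float = 0.5
    amp_mean_pa: float = 30.0     # mean of the log-normal amplitude distribution
    amp_sigma_ln: float = 0.35    # sigma of log(amplitude)
    burst_rate_hz: float = 0.0    # burst-epoch arrival rate
    within_burst_rate_hz: float = 80.0
    burst_duration_mean_s: float = 2.0
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 10.0

    def __post_init__(self) -> None:
        for name in ("base_rate_hz", "burst_rate_hz", "within_burst_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise must be < tau_decay")


@dataclass
class ConditionSpec:
    """Generative description of one cohort condition (genotype × week)."""

    genotype: str
    week: int
    params_mean: NeuronParams
    params_cv: dict = field(default_factory=dict)  # field name -> coefficient of variation
    synaptic: SynapticInputStats = field(default_factory=SynapticInputStats)


@dataclass
class CohortSpec:
    """Full cohort recipe: conditions, group size, protocols, master seed."""

    conditions: list[ConditionSpec]
    n_per_condition: int = 20
    master_seed: int = 0
    cc_protocol: ProtocolSpec | None = None
    vc_protocol: ProtocolSpec | None = None
    gapfree_duration_s: float = 150.0
    gapfree_fs: float = 5000.0
    noise_sd_pa: float = 2.0

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
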