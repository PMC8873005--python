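"""Simulator contracts: closed forms, determinism, preset orderings."""

import numpy as np
import pytest

from patchphys import (
    NeuronParams,
    ProtocolSpec,
    SynapticInputStats,
    default_cohort_spec,
    generate_cohort,
    simulate_current_clamp,
    simulate_synaptic_recording,
    simulate_voltage_clamp,
)

from oracles import zero_crossing_count


FS = 10_000.0


class TestCurrentClamp:
    def test_passive_rc_closed_form(self, passive_params, cc_protocol):
        """With g_Na=g_Kd=g_A=0 the step response is the RC closed form:
        ΔV = I/g_L and τ = C_m/g_L, each within 1%."""
        proto = ProtocolSpec(mode="current_clamp_steps", step_amplitudes=[20.0])
        sw = simulate_current_clamp(passive_params, proto, seed=0)
        v = sw.traces[0].samples
        on = int(proto.step_onset * FS)
        off = int(proto.step_offset * FS)
        rest = v[on - 10]
        dv = v[off - 10] - rest
        assert dv == pytest.approx(20.0 / 2.0, rel=0.01)        # I/g_L = 10 mV
        # tau from the 1 - 1/e point
        target = rest + dv * (1 - np.exp(-1))
        idx = np.argmax(v[on:off] >= target)
        tau_ms = idx / FS * 1000.0
        assert tau_ms == pytest.approx(30.0 / 2.0, rel=0.01)    # C/g_L = 15 ms

    def test_zero_steps_rest_at_equilibrium(self, excitable_params):
        """Zero-amplitude steps leave every trace at rest (±0.5 mV) after
        the settling window."""
        proto = ProtocolSpec(mode="current_clamp_steps",
                             step_amplitudes=[0.0, 0.0])
        sw = simulate_current_clamp(excitable_params, proto, seed=0)
        for tr in sw.traces:
            v = tr.samples[int(0.2 * FS):]
            assert np.ptp(v) < 0.5

    def test_spike_count_matches_crossing_oracle(self, robust_spiker_params,
                                                  cc_protocol):
        """On a noiseless family of full-sized (overshooting) spikes the
        number of upward 0 mV crossings equals the detector's spike count,
        sweep by sweep."""
        from patchphys import detect_spikes

        sw = simulate_current_clamp(robust_spiker_params, cc_protocol, seed=1)
        proto = sw.protocol
        for tr in sw.traces:
            on = int(proto.step_onset * tr.fs)
            off = int(proto.step_offset * tr.fs)
            t = detect_spikes(tr)
            t = t[(t >= proto.step_onset) & (t < proto.step_offset)]
            crossings = zero_crossing_count(tr.samples[on:off])
            assert crossings == len(t)

    def test_wrong_mode_rejected(self, passive_params, vc_protocol):
        with pytest.raises(ValueError, match="current_clamp"):
            simulate_current_clamp(passive_params, vc_protocol, seed=0)

    def test_nonfinite_params_rejected(self, cc_protocol):
        with pytest.raises(ValueError):
            NeuronParams(g_na=np.nan)

    def test_determinism_bit_identical(self, excitable_params, cc_protocol):
        p = excitable_params.with_(noise_sd=2.0)
        a = simulate_current_clamp(p, cc_protocol, seed=42)
        b = simulate_current_clamp(p, cc_protocol, seed=42)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.samples, tb.samples)


class TestVoltageClamp:
    def test_leak_only_steady_current(self, passive_params, vc_protocol):
        """Passive cell: post-transient steady current is g_L(V−E_L) exactly."""
        sw = simulate_voltage_clamp(passive_params, vc_protocol, seed=0)
        for amp, tr in zip(vc_protocol.step_amplitudes, sw.traces):
            ss = tr.samples[int(0.25 * FS):int(0.29 * FS)].mean()
            assert ss == pytest.approx(2.0 * (amp - (-65.0)), abs=1e-6)

    def test_transient_charge_equals_c_dv(self, passive_params):
        """∫(transient above leak) = C_m·ΔV within 1%: 30 pF × 10 mV = 300 fC."""
        proto = ProtocolSpec(mode="voltage_clamp_steps", holding=-70.0,
                             step_amplitudes=[-60.0], step_onset=0.1,
                             step_offset=0.3, sweep_duration=0.4)
        sw = simulate_voltage_clamp(passive_params, proto, seed=0)
        x = sw.traces[0].samples
        on = int(0.1 * FS)
        leak = x[int(0.25 * FS):int(0.29 * FS)].mean()
        seg = x[on:on + int(0.01 * FS)] - leak
        q = np.trapezoid(seg) / FS * 1e3         # pA·s → fC
        # 2% headroom covers the trapezoid bias at ~3 samples per tau
        assert q == pytest.approx(30.0 * 10.0, rel=0.02)

    def test_na_peak_monotone_in_g_na(self, excitable_params, vc_protocol):
        """Doubling g_Na strictly increases the peak inward current."""
        a = simulate_voltage_clamp(excitable_params, vc_protocol, seed=0)
        b = simulate_voltage_clamp(excitable_params.with_(g_na=190.0),
                                   vc_protocol, seed=0)
        on = int(0.1 * FS)

        def peak_inward(sw):
            return min(tr.samples[on + 10:on + 100].min() for tr in sw.traces)

        assert peak_inward(b) < peak_inward(a) < 0

    def test_rs_zero_rejected(self, passive_params, vc_protocol):
        with pytest.raises(ValueError, match="r_s"):
            simulate_voltage_clamp(passive_params.with_(r_s=0.0),
                                   vc_protocol, seed=0)

    def test_determinism(self, excitable_params, vc_protocol):
        p = excitable_params.with_(noise_sd=2.0)
        a = simulate_voltage_clamp(p, vc_protocol, seed=7)
        b = simulate_voltage_clamp(p, vc_protocol, seed=7)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.samples, tb.samples)


class TestSynapticRecording:
    def test_zero_rate_flat(self):
        st = SynapticInputStats(base_rate_hz=0.0)
        tr, truth = simulate_synaptic_recording(st, 30.0, 5000.0, 0.0, seed=0)
        assert np.all(tr.samples == 0.0)
        assert len(truth.events) == 0

    def test_event_count_in_poisson_interval(self):
        """λ=0.5 Hz over 600 s: the count lies in the central 99% interval."""
        st = SynapticInputStats(base_rate_hz=0.5)
        _, truth = simulate_synaptic_recording(st, 600.0, 5000.0, 0.0, seed=1)
        lo, hi = 300 - 2.576 * np.sqrt(300), 300 + 2.576 * np.sqrt(300)
        assert lo <= len(truth.events) <= hi

    def test_single_event_peak_normalised(self):
        """One 30 pA event: the trace minimum is −30 pA within 1%."""
        st = SynapticInputStats(base_rate_hz=0.1, amp_mean_pa=30.0,
                                amp_sigma_ln=0.0)
        for seed in range(50):
            tr, truth = simulate_synaptic_recording(st, 10.0, 10_000.0, 0.0,
                                                    seed=seed)
            if len(truth.events) == 1:
                break
        assert len(truth.events) == 1
        assert tr.samples.min() == pytest.approx(-30.0, rel=0.01)

    def test_tau_order_validated(self):
        with pytest.raises(ValueError):
            SynapticInputStats(tau_rise_ms=10.0, tau_decay_ms=2.0)

    def test_low_fs_rejected(self):
        st = SynapticInputStats(tau_rise_ms=2.0, tau_decay_ms=10.0)
        with pytest.raises(ValueError, match="resolve"):
            simulate_synaptic_recording(st, 10.0, 1000.0, 0.0, seed=0)

    def test_determinism(self):
        st = SynapticInputStats(base_rate_hz=1.0)
        a, ta = simulate_synaptic_recording(st, 20.0, 5000.0, 2.0, seed=5)
        b, tb = simulate_synaptic_recording(st, 20.0, 5000.0, 2.0, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert ta.events.equals(tb.events)


class TestCohort:
    def test_same_seed_same_truth(self):
        s1 = default_cohort_spec(master_seed=3, n_per_condition=2)
        s2 = default_cohort_spec(master_seed=3, n_per_condition=2)
        s1.gapfree_duration_s = s2.gapfree_duration_s = 20.0
        c1 = generate_cohort(s1)
        c2 = generate_cohort(s2)
        assert c1.truth.equals(c2.truth)
        assert np.array_equal(c1.cells[0].cc.traces[0].samples,
                              c2.cells[0].cc.traces[0].samples)

    def test_preset_orderings(self):
        """Ground-truth parameter means follow the preset's phenotype axes."""
        spec = default_cohort_spec(master_seed=0, n_per_condition=20)
        spec.gapfree_duration_s = 10.0
        truth = generate_cohort(spec).truth
        g = truth.groupby(["week", "genotype"]).mean(numeric_only=True)

        # A-type conductance larger in week-7 mutant than control
        assert g.loc[(7, "mutant"), "g_a"] > g.loc[(7, "control"), "g_a"]
        # week-11 mutant has smaller Na/Kd and collapsed synaptic drive
        assert g.loc[(11, "mutant"), "g_na"] < g.loc[(11, "control"), "g_na"]
        ratio = (g.loc[(11, "mutant"), "syn_total_rate_hz"]
                 / g.loc[(11, "control"), "syn_total_rate_hz"])
        assert ratio <= 0.3

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            spec = default_cohort_spec(n_per_condition=0)
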