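"""Simulate a current-clamp step family and summarize excitability.

Builds one moderately excitable model neuron, runs the default step
protocol (−10…+60 pA, 400 ms steps), counts evoked action potentials per
step and measures the rheobase-spike shape.
"""

from patchphys import (NeuronParams, default_cc_protocol,
                       simulate_current_clamp, excitability_summary,
                       first_spike_features)

params = NeuronParams(c_m=28.0, g_l=1.2, g_na=95.0, g_kd=16.0, g_a=26.0,
                      noise_sd=2.0)
sweeps = simulate_current_clamp(params, default_cc_protocol(), seed=1)

ex = excitability_summary(sweeps)
sh = first_spike_features(sweeps)

print(f"per-step spike counts: {ex.per_step_counts}")
print(f"total evoked APs:      {ex.total_evoked}")
print(f"max APs in one step:   {ex.max_per_step}")
print(f"rheobase:              {ex.rheobase_pa:.0f} pA")
print(f"threshold:             {sh.threshold_mv:.1f} mV")
print(f"spike amplitude:       {sh.amplitude_mv:.1f} mV (peak - threshold)")
print(f"FWHM:                  {sh.fwhm_ms:.2f} ms")
print(f"fast AHP:              {sh.fahp_mv:.2f} mV (trough - threshold)")
# The counts quantify intrinsic excitability; the shape features describe
# the first spike evoked with minimal current, as used for group comparisons.
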