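"""Voltage-clamp current family: capacitance, leak, and Na/K I–V curves.

Simulates voltage steps (−90…+40 mV from −70 mV holding), estimates the
cell capacitance from the charging transient of the most hyperpolarized
step, subtracts the fitted linear leak, and extracts the peak Na (inward),
fast-K (transient outward) and slow-K (sustained outward) currents per
command voltage.
"""

from patchphys import (NeuronParams, default_vc_protocol,
                       simulate_voltage_clamp, estimate_capacitance,
                       extract_currents)

params = NeuronParams(c_m=28.0, g_l=1.2, g_na=95.0, g_kd=16.0, g_a=26.0,
                      noise_sd=2.0)
proto = default_vc_protocol()
sweeps = simulate_voltage_clamp(params, proto, seed=1)

cap = estimate_capacitance(sweeps.traces[0], dv_mv=-20.0,
                           onset_s=proto.step_onset)
feats = extract_currents(sweeps, capacitance_pf=cap)

print(f"capacitance:  {cap:.1f} pF  (ground truth {params.c_m} pF)")
print(f"leak fit:     g = {feats.leak_g_ns:.2f} nS, E = {feats.leak_e_mv:.1f} mV")
print()
print("V_cmd (mV)   Na peak (pA)   fast K (pA)   slow K (pA)")
for v, na, kf, ks in zip(feats.v_cmd_mv, feats.na_peak_pa,
                         feats.kfast_peak_pa, feats.kslow_pa):
    print(f"{v:9.0f} {na:14.0f} {kf:13.0f} {ks:13.0f}")
# Na current is inward (negative), maximal at intermediate depolarizations
# and vanishing toward E_Na; the K components grow with depolarization.
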