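# Methods

## The membrane model

Each simulated cell is a single compartment obeying

```
C_m dV/dt = −g_Na m³h (V − E_Na) − g_Kd n⁴ (V − E_K)
            − g_A a³b (V − E_K) − g_L (V − E_L) + I_inj(t) + ξ(t)
```

with units chosen so no conversion factors appear (pF, mV, ms, pA, nS:
pF·mV/ms = pA, nS·mV = pA).

Na and delayed-rectifier gates use the classic thermodynamic alpha/beta
rate functions shifted by a threshold parameter `vt` and scaled by a
common factor `rate_scale`:

* `vt = −55 mV` (default).  With the small absolute conductances of
  immature cultured neurons (tens of nS on 25–50 pF, versus thousands of
  nS for an adult neuron), the spike threshold measured by the
  dV/dt ≥ 10 mV/ms criterion sits ≈ 20–25 mV above `vt`, i.e. near
  −30 mV, the range reported for this preparation.
* `rate_scale = 0.8` slows all Na/Kd kinetics uniformly, broadening
  spikes toward the slow waveforms of immature neurons while keeping the
  upstroke above the detection criterion.

The A-type (fast, Kv1.5-like) conductance uses Boltzmann steady states —
activation `a` (midpoint −35 mV, slope 9 mV, τ = 1 ms, gate cubed) and
inactivation `b` (midpoint −62 mV, slope 7 mV, τ = 25 ms).  Because `a`
is fast and `b` slow, the channel passes a transient outward current
during the spike: raising `g_A` monotonically deepens the fast AHP,
narrows the spike, and raises the early transient outward current in
voltage clamp — the axis along which the two genotypes differ most in
this phenotyping problem.

Integration is exponential Euler for both gates and voltage at a fixed
0.025 ms step (well inside the stability range of these kinetics), with
output decimated to the recording rate (10 kHz for step protocols).  Each
sweep is preceded by a 200 ms unrecorded settling run at the holding
level, computed once per cell since it is noise-free.  Additive Gaussian
current noise (default 2 pA in cohorts) is held constant across the
sub-steps of each output sample.  The kernels are compiled with numba;
identical (parameters, protocol, seed) give bit-identical traces.

In voltage clamp the gating ODEs are integrated at the commanded
potential and the series-resistance charging transient is added
analytically at each step edge: amplitude ΔV/R_s, decay τ = R_s·C_m,
total charge exactly C_m·ΔV.  Sign convention: inward current negative.

## Synaptic-input model

Spontaneous EPSC trains are doubly stochastic Poisson processes: a
sparse base rate everywhere plus burst epochs (Poisson arrivals;
gamma-shaped durations, shape 4, so epochs are never vanishingly short)
during which the rate jumps to `within_burst_rate_hz`.  Amplitudes are
log-normal with specified mean; each event adds an inward biexponential
kernel `A(e^{−t/τ_d} − e^{−t/τ_r})` peak-normalised to −A (defaults
τ_r = 2 ms, τ_d = 10 ms).  The generator returns the trace together with
the ground-truth event and epoch tables, which is what makes detector
recall/precision and burst-recovery claims testable.

## Feature extraction

**Spike detection.** A spike is an upward crossing of dV/dt ≥ 10 mV/ms
whose voltage reaches ≥ −10 mV within 5 ms; crossings within a 2 ms
refractory period, or resolving to an already-used peak, are merged.  The
derivative is smoothed with a 0.5 ms boxcar — at 1 mV sample noise and
10 kHz the raw finite-difference derivative has ≈ 7 mV/ms noise SD, which
otherwise produces duplicate crossings.  Only spikes inside the stimulus
window count as evoked.

**Rheobase-spike shape.** On the lowest step that evokes a spike:
threshold = V at the start of the contiguous dV/dt ≥ criterion run before
the peak; amplitude = peak − threshold; FWHM at threshold + amplitude/2
with subsample interpolation; fast AHP = trough − threshold in a 20 ms
window opening when V falls back below threshold, truncated at the next
spike.  If V plateaus above threshold until the next spike there is no
trough and the fAHP is NaN, not a signed value.  All shape features are
threshold-referenced and therefore invariant to adding a constant to the
trace.  Note that with a slowly rising waveform the dV/dt criterion
places the threshold partway up the flank; analytic-geometry checks
(e.g. the Gaussian-bump FWHM) therefore use a low criterion where the
measured threshold coincides with the baseline.

**Capacitance.** From the onset transient of a hyperpolarizing step
(no channels open): the above-steady transient is tracked from onset to
5 % of its peak, its decay fitted log-linearly, and the fitted
exponential integrated analytically, C = Q/ΔV.  A plain trapezoid over
that span both truncates 5 % of the charge and suffers discretisation
bias at the ~3 samples per τ typical here (τ = R_s·C_m ≈ 0.3 ms at
10 kHz); the fit-and-integrate form is exact on a clean transient and
within 1 % at 5 pA noise.

**Leak subtraction and I–V extraction.** Leak is fitted as
I = g(V − E) on post-transient steady currents of steps at or below
−60 mV and subtracted piecewise (holding level included), so a constant
offset current is absorbed.  Per command voltage: Na peak = window
minimum 0.5–10 ms post-onset (clipped ≤ 0); slow K = mean over the last
50 ms of the step (clipped ≥ 0); fast K = early-window (2–25 ms) maximum
minus the slow-K level (clipped ≥ 0).  The subtraction isolates the
inactivating component: doubling `g_A` doubles the reported fast-K peak,
whereas a raw window maximum would mix in the delayed-rectifier steady
current.  Windows are parameters, not constants, because real protocols
vary.

**EPSC detection.** Baseline is the per-5 s-block median interpolated
across the recording; noise SD is the median of block MADs × 1.4826 —
both robust to event load and to a nonzero holding current.  Candidates
are peaks of the 0.6 ms-smoothed inward deflection exceeding 3×SD in both
height and prominence (prominence suppresses ripples on decay tails) with
a 2 ms spacing.  Each candidate must pass kinetic bounds — 10–90 % rise
0.5–5 ms, 1/e decay 3–50 ms, decay > rise — measured relative to the
valley since the previous event, so stacked within-burst events are
evaluated correctly; decays truncated by a following event are accepted.
Amplitude is the baseline-referenced smoothed deflection at the peak
(a windowed maximum over the raw trace would carry a max-of-noise bias
of several pA).

**Bursts.** A network burst is a maximal run of ≥ 3 consecutive events
with all inter-event intervals ≤ 100 ms; duration is last-minus-first
event time; the burst rate is bursts per recording duration; interburst
intervals are the gaps between consecutive bursts (undefined with < 2
bursts).  Applied to true event times the segmentation recovers generated
epochs nearly exactly; applied to *detected* trains from recordings with
heavy within-burst summation it fragments bursts (≈ +30 % count, shorter
durations).  Group contrasts of burst statistics are robust to this
because both conditions are fragmented alike, but absolute burst counts
from detected trains should be read with that bias in mind.

## Cohort statistics

Two-group comparisons default to Student's pooled-variance two-tailed
t-test; reconstructing published results from (mean, SEM, n) summaries
uses sd = sem·√n and the same pooled formula (a Welch option exists).
The pooled form, not Welch, reproduces the worked published-style
examples: (14.6 ± 2, n = 7) vs (4.7 ± 0.8, n = 7) → p = 6.2e−4, and
(35 ± 5, n = 37) vs (12 ± 3, n = 14) → p = 0.0084.  When a feature is not
measurable in every cell the per-measure n is smaller than the cohort n,
which is the usual reason reconstructed and published p-values disagree
slightly.  No multiple-testing correction is applied by default (per-
measure p-values are reported as-is, the field's convention for this
kind of phenotyping table); Benjamini–Hochberg can be applied downstream.
Star codes use strict inequalities (p = 0.05 → "ns").  Amplitude
distributions are compared with the two-sample KS statistic plus the
sign of the median shift ("right-shifted" = larger amplitudes).  The
trajectory grid runs every measure × week through the same comparison
and records the sign of (mutant − control).

## The default cohort preset

Conditions are genotype × week (5, 7, 11) with per-cell parameters drawn
log-normally around condition means (unit mean; CV 0.15–0.18 for
conductances and capacitance, 0.3 for synaptic base rate).  Means encode
the phenotype axes, with capacitance maturing identically in both
genotypes (25 → 28 → 52 pF):

| week | condition | g_Na | g_Kd | g_A | g_L | synaptic drive |
|-----:|-----------|-----:|-----:|----:|----:|----------------|
| 5  | control | 50  | 9  | 8  | 1.0 | 0.10 Hz, 20 pA |
| 5  | mutant  | 80  | 14 | 22 | 1.0 | 0.12 Hz, 30 pA |
| 7  | control | 80  | 12 | 8  | 1.2 | 0.25 Hz, 25 pA |
| 7  | mutant  | 92  | 17 | 36 | 1.2 | 0.25 Hz, 27 pA |
| 11 | control | 190 | 32 | 25 | 2.0 | 1.0 Hz + bursts (0.05 Hz, 1.5 s, 60 Hz) |
| 11 | mutant  | 140 | 24 | 20 | 2.0 | 0.25 Hz + bursts (0.008 Hz, 0.6 s, 60 Hz) |

(conductances in nS.)  The week-11 mutant synaptic drive is ≈ 0.10× the
control event rate, 0.16× the burst-epoch rate with 6.25× the epoch
spacing and 60 %-shorter bursts.  These numbers are implementation
defaults calibrated on the model itself: contrasts were widened (within
the fixed orderings above) until the full qualitative maturation pattern
— mutant excitability above control at week 5 and below at week 11,
deeper mutant fAHP and narrower FWHM at weeks 5 and 7, collapsed mutant
synaptic/burst activity at week 11 — is recovered by the complete
pipeline in 20/20 master seeds at n = 20 cells per condition.  Cohort
recordings use 150 s of gap-free time per cell at 5 kHz and 2 pA noise;
150 s is the shortest duration at which most mutant week-11 cells still
contain ≥ 2 bursts, keeping per-cell interburst intervals defined.

Per-cell seeds are spawned from one master `SeedSequence` in a fixed
order, so a cohort is a pure function of its spec.

## What the generator does and does not emulate

It emulates: step-evoked spiking whose count and shape depend on
condition; voltage-step current families with capacitive transients and
leak; sparse-to-bursty spontaneous EPSC trains; stationary Gaussian
recording noise.  It does not emulate: electrode-access drift, seal
instability or series-resistance changes; dendritic filtering
(single compartment); slow adaptation currents — at strong drive model
cells fire faster tonic trains than real immature neurons, so absolute
evoked-spike totals run higher than published ranges even though every
between-condition ordering is preserved; mechanistic network bursts
(burst structure is statistical); IPSC/EPSC pharmacological separation.
Passing tests therefore demonstrate correctness of the analysis chain
and internal consistency of condition contrasts, not biological fidelity
of absolute firing rates.

## Numerical and degenerate-input conventions

All times are seconds at the API surface (rates in Hz), voltages mV,
currents pA, capacitance pF, conductances nS; readers validate units.
Rheobase ties break by sweep order.  Zero-variance groups with equal
means give t = 0, p = 1; with unequal means p = 0 with a flag.  Empty
event lists give rate 0 and NaN amplitude statistics.  Cells with no
spikes keep valid excitability counts but NaN shape features, with a QC
flag; the pipeline records per-cell failures rather than aborting.
Trace files round-trip losslessly (17-significant-digit CSV with
round-trip float parsing; uniform-sampling check at 1 ppm).
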