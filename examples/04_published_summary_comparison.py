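"""Two-group inference directly from published summary statistics.

When only mean ± SEM and n are available (as printed in a paper), the
pooled-variance t-test can be reconstructed without raw data.
"""

from patchphys import SummaryStat, compare_from_summary, percent_change

# fraction of GABA-expressing neurons in two culture conditions (%)
control = SummaryStat(mean=14.6, sem=2.0, n=7)
mutant = SummaryStat(mean=4.7, sem=0.8, n=7)
c = compare_from_summary(control, mutant, measure="GABA+ fraction")
print(f"GABA+ fraction: t = {c.t:.2f}, df = {c.df:.0f}, "
      f"p = {c.p:.1e} {c.stars}")
print(f"  change vs control: {c.percent_change:+.0f}%")

# total evoked APs per cell in two groups of different size
g1 = SummaryStat(mean=12.0, sem=3.0, n=14)
g2 = SummaryStat(mean=35.0, sem=5.0, n=37)
c2 = compare_from_summary(g1, g2, measure="total evoked APs")
print(f"total evoked:   t = {c2.t:.2f}, df = {c2.df:.0f}, "
      f"p = {c2.p:.3f} {c2.stars}")
print(f"  burst-rate style changes: {percent_change(1.0, 0.14):+.0f}% "
      f"(a 7x reduction), {percent_change(1.0, 7.0):+.0f}% (a 7x increase)")
# The star code follows the usual convention: * p<0.05, ** p<0.01,
# *** p<0.001, **** p<0.0001 (strict inequalities).
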