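"""Cohort-level inference: two-group comparisons and maturation trajectories.

The default test is Student's pooled-variance two-sample two-tailed t-test
(a Welch option is available).  Comparisons can be run either from raw
per-cell values or from published summary statistics (mean, SEM, n), in
which case the group standard deviation is reconstructed as ``sem·√n``.
Significance is annotated with the conventional star code:
**** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05, ns otherwise — all
strict inequalities, so a p exactly at a boundary gets the weaker code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "SummaryStat",
    "maturation_pattern",
    "plot_trajectory",
    "GroupComparison",
    "compare_groups",
    "compare_from_summary",
    "percent_change",
    "stars",
    "compare_ecdfs",
    "trajectory_table",
    "TRAJECTORY_MEASURES",
]


@dataclass(frozen=True)
class SummaryStat:
    """Published-style group summary: mean ± SEM with group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics require n >= 2")
        if self.sem < 0 or not np.isfinite(self.sem):
            raise ValueError("sem must be finite and >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_values(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("need >= 2 finite values")
        return cls(mean=float(x.mean()),
                   sem=float(x.std(ddof=1) / np.sqrt(x.size)),
                   n=int(x.size))


@dataclass
class GroupComparison:
    measure: str
    control: SummaryStat
    treated: SummaryStat
    t: float
    df: float
    p: float
    percent_change: float    # treated vs control
    stars: str
    zero_variance: bool = False


def stars(p: float) -> str:
    """Map a p-value to the conventional significance code (strict bounds)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def _pooled_t(a: SummaryStat, b: SummaryStat) -> tuple[float, float, float, bool]:
    """Pooled-variance t statistic for b vs a → (t, df, p, zero_variance)."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if se == 0:
        if b.mean == a.mean:
            return 0.0, float(df), 1.0, True
        return np.inf if b.mean > a.mean else -np.inf, float(df), 0.0, True
    t = (b.mean - a.mean) / se
    p = 2.0 * sst.t.sf(abs(t), df)
    return float(t), float(df), float(p), False


def compare_groups(
    a, b, measure: str = "", welch: bool = False
) -> GroupComparison:
    """Two-sample two-tailed t-test between per-cell value arrays.

    ``a`` is the reference (control) group; the reported t, sign and
    percent change describe ``b`` relative to ``a``.  Non-finite values
    are dropped.  Student's pooled-variance test by default; set
    ``welch=True`` for the unequal-variance variant.
    """
    sa = SummaryStat.from_values(a)
    sb = SummaryStat.from_values(b)
    if welch:
        av = np.asarray(a, float)
        bv = np.asarray(b, float)
        res = sst.ttest_ind(bv[np.isfinite(bv)], av[np.isfinite(av)],
                            equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        zero = not np.isfinite(t)
    else:
        t, df, p, zero = _pooled_t(sa, sb)
    pct = percent_change(sa.mean, sb.mean) if sa.mean != 0 else np.nan
    return GroupComparison(measure=measure, control=sa, treated=sb,
                           t=t, df=df, p=p, percent_change=pct,
                           stars=stars(min(max(p, 0.0), 1.0)),
                           zero_variance=zero)


def compare_from_summary(
    a: SummaryStat, b: SummaryStat, measure: str = ""
) -> GroupComparison:
    """Pooled-variance t-test reconstructed from summary statistics.

    Reconstructs each group's SD as sem·√n and applies the pooled-t
    formula.  When the per-measure n differs from the reported cohort n
    (features are not measurable in every cell), the reconstructed p can
    differ from a published one computed on the actual per-measure n.
    """
    if a.sem <= 0 or b.sem <= 0:
        raise ValueError("published summaries must have sem > 0")
    t, df, p, zero = _pooled_t(a, b)
    pct = percent_change(a.mean, b.mean) if a.mean != 0 else np.nan
    return GroupComparison(measure=measure, control=a, treated=b,
                           t=t, df=df, p=p, percent_change=pct,
                           stars=stars(min(max(p, 0.0), 1.0)),
                           zero_variance=zero)


def compare_ecdfs(a, b) -> dict:
    """Two-sample KS comparison of amplitude distributions.

    Returns the KS statistic and the shift direction of ``b`` relative to
    ``a``: "right" when b's median is higher (larger amplitudes), "left"
    when lower, "none" when equal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = sst.ks_2samp(a, b)
    dmed = float(np.median(b) - np.median(a))
    direction = "right" if dmed > 0 else ("left" if dmed < 0 else "none")
    return {"ks": float(ks.statistic), "p": float(ks.pvalue),
            "direction": direction, "median_shift": dmed}


# measures shown in the maturation-summary grid, in display order
TRAJECTORY_MEASURES = [
    "total_evoked",
    "max_per_step",
    "fahp_mv",
    "amplitude_mv",
    "fwhm_ms",
    "threshold_mv",
    "capacitance_pf",
    "epsc_rate_hz",
    "epsc_amplitude_pa",
    "burst_rate_hz",
    "burst_duration_s",
    "interburst_interval_s",
]


def trajectory_table(
    features: pd.DataFrame,
    measures: list[str] | None = None,
    control_label: str = "control",
    treated_label: str = "mutant",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-measure × per-week comparison grid across maturation.

    ``features`` holds one row per cell with at least ``genotype`` and
    ``week`` columns plus the measure columns.  For each measure and week
    the grid reports both group summaries, pooled-t inference, the star
    code and the sign of (treated − control).  Measures with fewer than
    two finite values in either group at a week are reported as NaN rows
    rather than dropped.
    """
    if measures is None:
        measures = [m for m in TRAJECTORY_MEASURES if m in features.columns]
    required = {"genotype", "week"}
    if not required <= set(features.columns):
        raise ValueError(f"features table must have columns {required}")
    weeks = sorted(features["week"].unique())
    rows = []
    for week in weeks:
        sub = features[features["week"] == week]
        ctl = sub[sub["genotype"] == control_label]
        trt = sub[sub["genotype"] == treated_label]
        if ctl.empty or trt.empty:
            raise ValueError(f"missing {control_label}/{treated_label} cells "
                             f"at week {week}")
        for m in measures:
            row = {"measure": m, "week": week}
            try:
                cmp_ = compare_groups(ctl[m], trt[m], measure=m, welch=welch)
                row.update(
                    control_mean=cmp_.control.mean, control_sem=cmp_.control.sem,
                    control_n=cmp_.control.n,
                    mutant_mean=cmp_.treated.mean, mutant_sem=cmp_.treated.sem,
                    mutant_n=cmp_.treated.n,
                    t=cmp_.t, df=cmp_.df, p=cmp_.p, stars=cmp_.stars,
                    percent_change=cmp_.percent_change,
                    direction=int(np.sign(cmp_.treated.mean - cmp_.control.mean)),
                )
            except ValueError:
                row.update(control_mean=np.nan, control_sem=np.nan,
                           control_n=int(np.isfinite(ctl[m]).sum()),
                           mutant_mean=np.nan, mutant_sem=np.nan,
                           mutant_n=int(np.isfinite(trt[m]).sum()),
                           t=np.nan, df=np.nan, p=np.nan, stars="ns",
                           percent_change=np.nan, direction=0)
            rows.append(row)
    return pd.DataFrame(rows)


def maturation_pattern(features: pd.DataFrame) -> dict:
    """Boolean checks of the developmental crossover phenotype.

    Evaluates, on cohort means, whether the mutant condition is
    hyperexcitable early and hypoexcitable late, with the accompanying
    spike-shape and synaptic signatures: total/max evoked spikes higher in
    mutant at week 5 and lower at week 11; deeper (more negative) fast AHP
    and narrower FWHM in mutant at weeks 5 and 7; and at week 11 lower
    EPSC rate, lower burst rate and longer interburst intervals in mutant.
    Returns one bool per check plus ``all`` for their conjunction.
    """
    g = features.groupby(["week", "genotype"]).mean(numeric_only=True)

    def mean(week, genotype, col):
        return g.loc[(week, genotype), col]

    checks = {
        "total_evoked_up_w5": mean(5, "mutant", "total_evoked")
                              > mean(5, "control", "total_evoked"),
        "max_per_step_up_w5": mean(5, "mutant", "max_per_step")
                              > mean(5, "control", "max_per_step"),
        "total_evoked_down_w11": mean(11, "mutant", "total_evoked")
                                 < mean(11, "control", "total_evoked"),
        "max_per_step_down_w11": mean(11, "mutant", "max_per_step")
                                 < mean(11, "control", "max_per_step"),
        "fahp_deeper_w5": mean(5, "mutant", "fahp_mv")
                          < mean(5, "control", "fahp_mv"),
        "fahp_deeper_w7": mean(7, "mutant", "fahp_mv")
                          < mean(7, "control", "fahp_mv"),
        "fwhm_narrower_w5": mean(5, "mutant", "fwhm_ms")
                            < mean(5, "control", "fwhm_ms"),
        "fwhm_narrower_w7": mean(7, "mutant", "fwhm_ms")
                            < mean(7, "control", "fwhm_ms"),
        "epsc_rate_down_w11": mean(11, "mutant", "epsc_rate_hz")
                              < mean(11, "control", "epsc_rate_hz"),
        "burst_rate_down_w11": mean(11, "mutant", "burst_rate_hz")
                               < mean(11, "control", "burst_rate_hz"),
        "interburst_longer_w11": mean(11, "mutant", "interburst_interval_s")
                                 > mean(11, "control", "interburst_interval_s"),
    }
    checks = {k: bool(v) for k, v in checks.items()}
    checks["all"] = all(checks.values())
    return checks


def plot_trajectory(grid: pd.DataFrame, measures: list[str] | None = None,
                    path: str | None = None):
    """Plot the maturation trajectory grid: one panel per measure,
    mean ± SEM per genotype against week.  Returns the figure; saves to
    ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = measures or list(dict.fromkeys(grid["measure"]))
    ncols = min(4, len(measures))
    nrows = -(-len(measures) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax, m in zip(axes.flat, measures):
        sub = grid[grid["measure"] == m].sort_values("week")
        for label, color in (("control", "tab:gray"), ("mutant", "tab:red")):
            ax.errorbar(sub["week"], sub[f"{label}_mean"],
                        yerr=sub[f"{label}_sem"], marker="o", capsize=3,
                        label=label, color=color)
        for _, row in sub.iterrows():
            if row["stars"] != "ns":
                ax.annotate(row["stars"], (row["week"],
                            max(row["control_mean"], row["mutant_mean"])),
                            ha="center", fontsize=8)
        ax.set_title(m, fontsize=9)
        ax.set_xlabel("week")
    for ax in axes.flat[len(measures):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
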