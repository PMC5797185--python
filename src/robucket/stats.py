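"""Cohort statistics for between-genotype comparisons.

Inference follows the conventions of small-cohort behavioral
phenotyping: Welch's unequal-variance t-test for group differences,
Cohen's d on the pooled SD for effect size, and analytic post-hoc power
for the two-sample t-test from the noncentral t distribution. Note the
deliberate asymmetry: power uses the classical pooled (equal-variance)
noncentral-t formulation — the convention of standard power calculators
— while the reported test statistic is Welch-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TTestResult",
    "PowerResult",
    "welch_t",
    "cohens_d",
    "power_t2n",
    "percent_reduction",
    "cohort_report",
]


@dataclass(frozen=True)
class GroupSample:
    """One group's per-mouse values."""

    label: str
    values: tuple[float, ...]

    def __init__(self, label: str, values: Sequence[float]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def var(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float


@dataclass(frozen=True)
class PowerResult:
    d: float
    n1: int
    n2: int
    alpha: float
    power: float


def _check_group(g: GroupSample) -> None:
    if g.n < 2:
        raise ValueError(f"group {g.label!r} needs n >= 2, got {g.n}")


def welch_t(a: GroupSample, b: GroupSample) -> TTestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with
    Welch–Satterthwaite degrees of freedom.
    """
    _check_group(a)
    _check_group(b)
    if a.var == 0 and b.var == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = sps.ttest_ind(a.values, b.values, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p_two_sided=float(res.pvalue))


def cohens_d(a: GroupSample, b: GroupSample, *, hedges: bool = False) -> float:
    """Cohen's d: mean difference over the pooled standard deviation.

    ``hedges=True`` applies the small-sample bias correction
    ``1 - 3/(4*(n1+n2) - 9)``; the uncorrected value is the default.
    """
    _check_group(a)
    _check_group(b)
    n1, n2 = a.n, b.n
    pooled_var = ((n1 - 1) * a.var + (n2 - 1) * b.var) / (n1 + n2 - 2)
    if pooled_var == 0:
        if a.mean == b.mean:
            return 0.0
        raise ValueError("zero pooled variance with unequal means; d is undefined")
    d = (a.mean - b.mean) / math.sqrt(pooled_var)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return d


def power_t2n(d: float, n1: int, n2: int, alpha: float = 0.05) -> PowerResult:
    """Analytic power of the two-sided two-sample t-test at effect size d.

    Uses the noncentral t distribution with noncentrality
    ``d * sqrt(n1*n2/(n1+n2))`` and ``n1 + n2 - 2`` degrees of freedom;
    power is the mass of the noncentral t beyond the two-sided central-t
    critical values.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must each be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))
    return PowerResult(d=d, n1=n1, n2=n2, alpha=alpha, power=power)


def percent_reduction(reference_mean: float, comparison_mean: float) -> float:
    """Percent reduction of ``comparison_mean`` relative to
    ``reference_mean``: ``100 * (ref - comp) / ref``."""
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (reference_mean - comparison_mean) / reference_mean


# ---------------------------------------------------------------------------
# cohort report


def _mouse_metrics(summaries: pd.DataFrame, progress: pd.DataFrame) -> pd.DataFrame:
    """One row per mouse, one column per metric (phase-pooled ratios,
    per-session means, days to criteria, stabilized breakpoint)."""
    rows = []
    for mouse_id, g in summaries.groupby("mouse_id", sort=False):
        row: dict[str, object] = {"mouse_id": mouse_id, "genotype": g["genotype"].iloc[0]}
        for phase in ("FR1", "FR5", "PR"):
            gp = g[g["phase"] == phase]
            if gp.empty:
                continue
            key = phase.lower()
            act, inact = gp["active_pokes"].sum(), gp["inactive_pokes"].sum()
            row[f"{key}_active_inactive_ratio"] = (
                act / inact if inact > 0 else (math.inf if act > 0 else math.nan)
            )
            row[f"{key}_total_pokes"] = gp["total_pokes"].mean()
            if phase == "PR":
                row["pr_rewards_per_session"] = gp["rewards"].mean()
        rows.append(row)
    metrics = pd.DataFrame(rows)
    prog_cols = progress[
        ["mouse_id", "fr1_days_to_criteria", "excluded", "pr_stabilization_day", "breakpoint"]
    ]
    return metrics.merge(prog_cols, on="mouse_id", how="left")


_REPORT_METRICS = [
    ("fr1_days_to_criteria", "FR1 days to criteria"),
    ("fr1_active_inactive_ratio", "FR1 active:inactive ratio"),
    ("fr1_total_pokes", "FR1 total pokes/session"),
    ("fr5_active_inactive_ratio", "FR5 active:inactive ratio"),
    ("fr5_total_pokes", "FR5 total pokes/session"),
    ("pr_stabilization_day", "PR days to criterion"),
    ("pr_active_inactive_ratio", "PR active:inactive ratio"),
    ("pr_total_pokes", "PR total pokes/session"),
    ("pr_rewards_per_session", "PR rewards/session"),
    ("breakpoint", "Stabilized breakpoint"),
]


def cohort_report(
    summaries: pd.DataFrame,
    progress: pd.DataFrame,
    *,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Per-metric group comparison table.

    One row per metric with group means, Welch t/df/p, Cohen's d and the
    percent reduction of the comparison group relative to ``reference``
    (default: the first genotype appearing in ``progress``). With a
    single genotype, or fewer than two finite values in a group, the
    comparison columns are left missing rather than raising.
    """
    mm = _mouse_metrics(summaries, progress)
    genotypes = list(dict.fromkeys(progress["genotype"]))
    if reference is None:
        reference = genotypes[0]
    others = [g for g in genotypes if g != reference]
    comparison = others[0] if others else None

    rows = []
    for col, name in _REPORT_METRICS:
        if col not in mm.columns:
            continue
        vals = {
            g: mm.loc[(mm["genotype"] == g), col].astype(float).replace([np.inf, -np.inf], np.nan).dropna()
            for g in genotypes
        }
        row: dict[str, object] = {"metric": name}
        for g in genotypes:
            row[f"mean_{g}"] = vals[g].mean() if len(vals[g]) else math.nan
            row[f"n_{g}"] = len(vals[g])
        if comparison is not None and len(vals[reference]) >= 2 and len(vals[comparison]) >= 2:
            a = GroupSample(reference, vals[reference])
            b = GroupSample(comparison, vals[comparison])
            try:
                tt = welch_t(a, b)
                row.update(t=tt.t, df=tt.df, p=tt.p_two_sided)
            except ValueError:
                row.update(t=math.nan, df=math.nan, p=math.nan)
            try:
                row["d"] = cohens_d(a, b)
            except ValueError:
                row["d"] = math.nan
            row["pct_reduction"] = (
                percent_reduction(a.mean, b.mean) if a.mean != 0 else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
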