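"""Condition-level aggregation and comparison of permeability reports.

Replicates (donors) are the unit of replication: image reports are averaged
within each replicate first, then summarised as mean +- SEM across
replicates. Conditions are compared metric-by-metric with the classical
pooled-variance (Student) unpaired t test, two-sided, with significance
stars at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "summarize",
    "unpaired_t_test",
    "percent_change",
    "significance_stars",
    "METRICS",
]

METRICS = ["fraction_permeable", "total_accumulation", "tj_fraction", "mean_per_permeable"]


@dataclass
class ConditionSummary:
    condition: str
    metric: str
    replicate_means: np.ndarray
    mean: float
    sem: float
    n_replicates: int


@dataclass
class ComparisonResult:
    metric: str
    condition_a: str
    condition_b: str
    t_statistic: float
    p_value: float
    stars: str
    degenerate: bool = False


def summarize(
    reports: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
) -> List[ConditionSummary]:
    """Mean +- SEM per condition, averaging images within replicates first.

    ``reports`` holds one row per image with metric columns plus condition
    and replicate labels. SEM is the sample SD of replicate means divided by
    sqrt(n_replicates).
    """
    if reports.empty:
        raise ValueError("no reports to summarise")
    out: List[ConditionSummary] = []
    for cond, group in reports.groupby(condition_col, sort=False):
        rep_means = group.groupby(replicate_col)[list(metrics)].mean()
        if rep_means.isna().any().any():
            raise ValueError(f"condition {cond!r} has replicates with missing metrics")
        n = len(rep_means)
        for metric in metrics:
            vals = rep_means[metric].to_numpy(float)
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            out.append(
                ConditionSummary(
                    condition=str(cond), metric=metric, replicate_means=vals,
                    mean=float(vals.mean()), sem=sem, n_replicates=n,
                )
            )
    return out


def summaries_to_frame(summaries: List[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": s.condition, "metric": s.metric, "mean": s.mean,
                "sem": s.sem, "n_replicates": s.n_replicates,
            }
            for s in summaries
        ]
    )


def significance_stars(p_value: float) -> str:
    """Strict-threshold stars: p < 0.05 -> *, < 0.01 -> **, < 0.001 -> ***."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def unpaired_t_test(
    a: Sequence[float], b: Sequence[float],
    metric: str = "", condition_a: str = "a", condition_b: str = "b",
) -> ComparisonResult:
    """Classical pooled-variance two-sample t test, two-sided.

    ``t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b))`` with the pooled
    variance on ``n_a + n_b - 2`` degrees of freedom. Zero pooled variance
    with equal means gives p = 1; with different means the comparison is
    flagged degenerate (p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 replicates")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return ComparisonResult(metric, condition_a, condition_b, 0.0, 1.0, "ns")
        return ComparisonResult(
            metric, condition_a, condition_b, np.inf if diff > 0 else -np.inf,
            0.0, "***", degenerate=True,
        )
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(metric, condition_a, condition_b, float(t), float(p),
                            significance_stars(p))


def percent_change(reference: float, treated: float) -> float:
    """Signed percent change of ``treated`` relative to ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (treated - reference) / reference


def compare_conditions(
    reports: pd.DataFrame,
    pairs: Sequence[tuple],
    metrics: Sequence[str] = METRICS,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """t tests on replicate means for each (condition_a, condition_b) pair."""
    summaries = summarize(reports, metrics, condition_col, replicate_col)
    by_key: Dict[tuple, ConditionSummary] = {
        (s.condition, s.metric): s for s in summaries
    }
    rows = []
    for ca, cb in pairs:
        for metric in metrics:
            sa, sb = by_key[(ca, metric)], by_key[(cb, metric)]
            res = unpaired_t_test(
                sa.replicate_means, sb.replicate_means, metric, ca, cb
            )
            rows.append(
                {
                    "metric": metric, "condition_a": ca, "condition_b": cb,
                    "mean_a": sa.mean, "mean_b": sb.mean,
                    "percent_change": percent_change(sa.mean, sb.mean),
                    "t_statistic": res.t_statistic, "p_value": res.p_value,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


def plot_condition_bars(summaries: List[ConditionSummary], metric: str, ax=None):
    """Bar chart of condition means with SEM error bars (cosmetic)."""
    import matplotlib.pyplot as plt

    subset = [s for s in summaries if s.metric == metric]
    if ax is None:
        _, ax = plt.subplots()
    names = [s.condition for s in subset]
    ax.bar(names, [s.mean for s in subset], yerr=[s.sem for s in subset],
           capsize=4, color="#7f9fc4")
    ax.set_ylabel(metric)
    return ax
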