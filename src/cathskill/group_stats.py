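"""Nonparametric expert-vs-novice comparison of per-phase metrics.

Every (task, phase, metric) cell is compared between the two experience
groups with the two-sided Wilcoxon rank-sum (Mann–Whitney) test, with
median and interquartile-range summaries per group and significance flags
at P < 0.05 and P < 0.001.  Each trial is treated as an independent
observation, matching the study design; no multiple-testing correction is
applied (none was in the original analysis) — reports state both choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonRow",
    "rank_sum_test",
    "summarize",
    "compare_groups",
    "comparison_frame",
]

#: exact-null enumeration is used up to this combined sample size (tie-free)
_EXACT_LIMIT = 12


@dataclass(frozen=True)
class ComparisonRow:
    """Expert-vs-novice comparison of one metric in one phase of one task."""

    task: str
    phase: str
    metric: str
    unit: str
    expert_median: float
    expert_q1: float
    expert_q3: float
    novice_median: float
    novice_q1: float
    novice_q3: float
    p_value: float
    significant: bool
    highly_significant: bool
    testable: bool = True


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    The null distribution is enumerated exactly for tie-free samples of
    combined size ≤ 12; larger or tied samples use the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= _EXACT_LIMIT and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def summarize(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the linear-interpolation quantile rule."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires a non-empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def compare_groups(
    metric_records: pd.DataFrame,
    labels: Mapping[str, str],
    alpha: float = 0.05,
    strong_alpha: float = 0.001,
) -> list[ComparisonRow]:
    """One comparison row per (task, phase, metric).

    ``metric_records`` is the long-format frame with columns
    ``trial_id, task, phase, metric, value, unit``; ``labels`` maps
    trial_id to 'expert' or 'novice'.  Rows are emitted for every metric
    (filtering to significant-only is a reporting option).  Cells with
    fewer than two trials in either group, or with all values identical,
    are marked untestable.
    """
    df = metric_records.copy()
    df["skill"] = df["trial_id"].map(labels)
    if df["skill"].isna().any():
        missing = df.loc[df["skill"].isna(), "trial_id"].unique()[:5]
        raise ValueError(f"no skill label for trials: {list(missing)}")
    rows: list[ComparisonRow] = []
    for (task, phase, metric), cell in df.groupby(
        ["task", "phase", "metric"], sort=True
    ):
        unit = cell["unit"].iloc[0]
        ex = cell.loc[cell["skill"] == "expert", "value"].to_numpy()
        nov = cell.loc[cell["skill"] == "novice", "value"].to_numpy()
        if ex.size < 2 or nov.size < 2:
            raise ValueError(
                f"need >=2 trials per group for {task}/{phase}/{metric}"
            )
        e_med, e_q1, e_q3 = summarize(ex)
        n_med, n_q1, n_q3 = summarize(nov)
        degenerate = np.unique(np.concatenate([ex, nov])).size == 1
        if degenerate:
            p = float("nan")
            testable = False
        else:
            p = rank_sum_test(ex, nov)
            testable = True
        rows.append(
            ComparisonRow(
                task=task,
                phase=phase,
                metric=metric,
                unit=unit,
                expert_median=e_med,
                expert_q1=e_q1,
                expert_q3=e_q3,
                novice_median=n_med,
                novice_q1=n_q1,
                novice_q3=n_q3,
                p_value=p,
                significant=testable and p < alpha,
                highly_significant=testable and p < strong_alpha,
                testable=testable,
            )
        )
    return rows


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame (CSV-ready)."""
    return pd.DataFrame([r.__dict__ for r in rows])


def loo_operator_sensitivity(
    metric_records: pd.DataFrame,
    labels: Mapping[str, str],
    operators: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Leave-one-operator-out sensitivity of the significance flags.

    The main analysis treats every trial as independent even though
    repetitions share an operator.  This check recomputes every comparison
    with each operator's trials removed in turn and reports, per (task,
    phase, metric), the worst-case (largest) p-value and whether the
    P < alpha call survives every leave-out.  Off by default in reports.
    """
    results: dict[tuple, dict] = {}
    all_ops = sorted(set(operators.values()))
    for op in all_ops:
        keep = metric_records[
            metric_records["trial_id"].map(operators) != op
        ]
        for row in compare_groups(keep, labels, alpha=alpha):
            key = (row.task, row.phase, row.metric)
            slot = results.setdefault(
                key, {"max_p_value": -np.inf, "always_significant": True}
            )
            p = row.p_value if row.testable else np.nan
            if np.isnan(p) or p > slot["max_p_value"]:
                slot["max_p_value"] = p
            slot["always_significant"] &= bool(row.significant)
    return pd.DataFrame(
        [
            {"task": k[0], "phase": k[1], "metric": k[2], **v}
            for k, v in sorted(results.items())
        ]
    )
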