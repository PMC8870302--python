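"""Cross-state statistics: paired t-tests and change rates over subjects.

Comparisons are paired by subject. The t statistic follows the A - B
difference convention: t < 0 means state B is larger on average. Change
rates are (mean_B - mean_A) / mean_A * 100, i.e. the percent change of the
comparison state relative to the reference state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StateComparison",
    "paired_ttest",
    "change_rate",
    "summarize_states",
    "compare_states",
]


@dataclass
class StateComparison:
    """A paired comparison of one metric between two states."""

    metric_name: str
    state_pair: tuple[str, str]
    n_subjects: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    mean_change_rate: float  # percent, (mean_b - mean_a) / mean_a * 100


def paired_ttest(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on subject-matched values.

    Identical inputs (all differences exactly zero) return (0.0, 1.0);
    zero-variance nonzero differences are degenerate and raise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = a - b
    if np.std(d) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError(
            "differences have zero variance but nonzero mean; the t statistic "
            "is unbounded (constant shift between states)"
        )
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def change_rate(mean_a: float, mean_b: float) -> float:
    """Percent change of B relative to A."""
    if mean_a == 0:
        return float("nan")
    return (mean_b - mean_a) / mean_a * 100.0


def summarize_states(
    table: pd.DataFrame,
    metric_columns: list[str],
    state_column: str = "state",
) -> pd.DataFrame:
    """Mean and standard deviation per state per metric, plus the formatted
    ``m +/- sd`` string used in reports.

    The sample standard deviation (ddof=1) is used; a single subject gives 0.
    """
    rows = []
    for state, grp in table.groupby(state_column, sort=False):
        for m in metric_columns:
            vals = grp[m].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            mean = float(vals.mean()) if vals.size else float("nan")
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                {
                    "state": state,
                    "metric": m,
                    "n": int(vals.size),
                    "mean": mean,
                    "sd": sd,
                    "formatted": f"{mean:.4f} ± {sd:.4f}",
                }
            )
    return pd.DataFrame(rows)


def compare_states(
    table: pd.DataFrame,
    metric: str,
    state_a: str,
    state_b: str,
    subject_column: str = "subject",
    state_column: str = "state",
) -> StateComparison:
    """Paired comparison of ``metric`` between two states across subjects.

    Subjects missing in either state (or with NaN metric values, e.g. an
    undefined path length) are dropped pairwise with a warning.
    """
    for s in (state_a, state_b):
        if s not in set(table[state_column]):
            raise ValueError(f"state '{s}' not present in table")
    pivot = table.pivot_table(
        index=subject_column, columns=state_column, values=metric,
        aggfunc="first", dropna=False,
    )
    pair = pivot[[state_a, state_b]].dropna()
    dropped = len(pivot) - len(pair)
    if len(pair) < 2:
        raise ValueError(
            f"{metric} {state_a} vs {state_b}: fewer than 2 subjects with "
            "paired values (metric undefined in one state?)"
        )
    if dropped:
        warnings.warn(
            f"{metric} {state_a} vs {state_b}: dropped {dropped} subject(s) "
            "missing a paired value",
            stacklevel=2,
        )
    a = pair[state_a].to_numpy(dtype=float)
    b = pair[state_b].to_numpy(dtype=float)
    t, p = paired_ttest(a, b)
    return StateComparison(
        metric_name=metric,
        state_pair=(state_a, state_b),
        n_subjects=len(pair),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t,
        p_value=p,
        mean_change_rate=change_rate(float(a.mean()), float(b.mean())),
    )
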