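"""Group summaries and significance tests on per-observer figures of
merit.

The analysis a free-response observer study typically reports: the
arithmetic group mean of each per-observer metric (FOM, sensitivity,
specificity), a pooled-variance two-sample t-test between independent
reader groups, and a paired t-test (one-sample t on after - before
differences) for repeated sessions of the same readers. All tests are
two-sided; no multiple-testing correction is applied, so callers running
several tests should say so in their reports (the CLI emits a note).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize_group",
    "unpaired_t_test",
    "paired_t_test",
]


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic means of per-observer metrics for one group.

    ``members`` retains the unrounded member values; ``means`` maps each
    numeric column to its arithmetic mean. Rounding is the reporting
    layer's job, not this one's.
    """

    group_label: str
    n: int
    means: Mapping[str, float]
    members: pd.DataFrame = field(repr=False)

    def _mean(self, *candidates: str) -> float:
        for c in candidates:
            if c in self.means:
                return self.means[c]
        raise KeyError(
            f"group {self.group_label!r} has none of columns {candidates}"
        )

    @property
    def mean_fom(self) -> float:
        return self._mean("fom")

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity", "sensitivity_points")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")


def summarize_group(
    group_label: str,
    members: pd.DataFrame | Sequence[Mapping[str, float]],
) -> GroupSummary:
    """Arithmetic mean of every numeric column over the group members."""
    frame = (
        members.copy()
        if isinstance(members, pd.DataFrame)
        else pd.DataFrame(list(members))
    )
    if len(frame) == 0:
        raise ContractError("summarize_group requires at least one member")
    means = frame.mean(numeric_only=True).to_dict()
    return GroupSummary(
        group_label=group_label,
        n=len(frame),
        means={k: float(v) for k, v in means.items()},
        members=frame,
    )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided t-test on per-observer FOMs.

    ``zero_variance`` flags the degenerate limit (no variability in the
    data): equal means give t = 0, p = 1; unequal means are reported as
    the p -> 0 limit with infinite t.
    """

    statistic: float
    df: float
    p_value: float
    kind: str
    alpha: float = 0.05
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ContractError(f"alpha {self.alpha} outside (0, 1)")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    *,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t-test between independent reader groups.

    Pooled (equal-variance) Student formulation by default, with
    ``equal_var=False`` switching to Welch. Two-sided p from the t
    distribution with n_a + n_b - 2 (pooled) or Welch-Satterthwaite df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return TestResult(0.0, df, 1.0, "unpaired", alpha, True)
        sign = math.copysign(1.0, a.mean() - b.mean())
        return TestResult(sign * math.inf, df, 0.0, "unpaired", alpha, True)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        kind="unpaired",
        alpha=alpha,
    )


def paired_t_test(
    before: Sequence[float],
    after: Sequence[float],
    alpha: float = 0.05,
) -> TestResult:
    """Paired t-test: one-sample t on the differences after - before.

    Values are paired positionally (same reader, two sessions); two-
    sided p with n - 1 degrees of freedom.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ContractError(
            f"length mismatch: {b.size} before vs {a.size} after"
        )
    if b.size < 2:
        raise ContractError("paired test needs at least 2 pairs")
    diff = a - b
    df = diff.size - 1
    if diff.std(ddof=1) == 0.0:
        if diff.mean() == 0.0:
            return TestResult(0.0, df, 1.0, "paired", alpha, True)
        sign = math.copysign(1.0, diff.mean())
        return TestResult(sign * math.inf, df, 0.0, "paired", alpha, True)
    res = stats.ttest_1samp(diff, 0.0)
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        kind="paired",
        alpha=alpha,
    )
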