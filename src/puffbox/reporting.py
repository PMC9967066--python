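"""Replicate aggregation and two-group comparison.

Replicate = one vaping experiment (one emission result).  Groups are
summarized as mean +/- standard error (sd/sqrt(n)) and compared with a
two-sided t-test at alpha = 0.05; Welch's unequal-variance variant is
the default since variances differ across device types, with Student's
pooled test available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("a group needs at least one value")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def standard_error(self) -> float:
        """sd/sqrt(n); NaN-flagged for a single replicate."""
        if self.n_replicates < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1) / np.sqrt(self.n_replicates))


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    variant: str
    degenerate: bool = False
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize_group(label: str, values) -> GroupSummary:
    return GroupSummary(label, tuple(values))


def compare_groups(
    a: GroupSummary, b: GroupSummary, variant: str = "welch"
) -> ComparisonResult:
    """Two-sided t-test between two replicate groups.

    Zero within-group variance with different means is a degenerate
    case: the statistic diverges, p is reported as 0 and the result is
    flagged.
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    if a.n_replicates < 2 or b.n_replicates < 2:
        raise ValueError("both groups need >= 2 replicates")
    va, vb = np.var(a.values, ddof=1), np.var(b.values, ddof=1)
    if va == 0 and vb == 0:
        if a.mean == b.mean:
            return ComparisonResult(a.label, b.label, 0.0, 1.0, variant, degenerate=True)
        return ComparisonResult(
            a.label, b.label, float("inf") if a.mean > b.mean else float("-inf"),
            0.0, variant, degenerate=True,
        )
    t, p = stats.ttest_ind(a.values, b.values, equal_var=(variant == "student"))
    return ComparisonResult(a.label, b.label, float(t), float(p), variant)
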