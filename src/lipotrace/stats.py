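"""Two-group summaries: mean ± SE with an unpaired t-test.

The default test is the pooled-variance (Student) unpaired t-test; Welch's
correction is available by flag. Significance markers follow the reporting
convention * p < 0.05, ** p < 0.01, and ¥ for 0.05 <= p < 0.10 ("strong
trend"). Benjamini-Hochberg adjustment across a table of metrics is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "summarize_groups", "significance_marker", "bh_adjust"]


@dataclass
class GroupSummary:
    metric: str
    groups: tuple[str, str]
    means: tuple[float, float]
    ses: tuple[float, float]
    ns: tuple[int, int]
    t_statistic: float | None
    p_value: float | None
    marker: str

    def as_row(self) -> dict:
        (g1, g2), (m1, m2), (s1, s2), (n1, n2) = self.groups, self.means, self.ses, self.ns
        return {
            "metric": self.metric,
            "group_1": g1,
            "mean_1": m1,
            "se_1": s1,
            "n_1": n1,
            "group_2": g2,
            "mean_2": m2,
            "se_2": s2,
            "n_2": n2,
            "t": self.t_statistic,
            "p": self.p_value,
            "significance": self.marker,
        }


def significance_marker(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "¥"
    return ""


def summarize_groups(
    values_by_group: dict[str, np.ndarray],
    metric: str = "",
    welch: bool = False,
) -> GroupSummary:
    """Mean, SE and two-sided unpaired t-test for exactly two groups.

    A group with fewer than two values yields a summary without a test,
    flagged by ``t_statistic is None``.
    """
    if len(values_by_group) != 2:
        raise ValueError("summarize_groups expects exactly two groups")
    (g1, v1), (g2, v2) = values_by_group.items()
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    means = (float(v1.mean()), float(v2.mean()))
    ses = tuple(
        float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else np.nan
        for v in (v1, v2)
    )
    if v1.size < 2 or v2.size < 2:
        return GroupSummary(metric, (g1, g2), means, ses, (v1.size, v2.size), None, None, "")
    if v1.var(ddof=1) == 0 and v2.var(ddof=1) == 0:
        # degenerate but well-defined limits: identical constants are a null
        # result, distinct constants an infinitely strong one
        t = 0.0 if means[0] == means[1] else np.inf * np.sign(means[0] - means[1])
        p = 1.0 if means[0] == means[1] else 0.0
    else:
        t, p = sps.ttest_ind(v1, v2, equal_var=not welch)
    return GroupSummary(
        metric,
        (g1, g2),
        means,
        ses,
        (v1.size, v2.size),
        float(t),
        float(p),
        significance_marker(float(p)),
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
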