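"""Shared statistics: t-test, chi-squared vs 1:1, Tukey HSD, box-plot stats.

These mirror the conventions standard in pollen-phenotyping figures: two-tailed
Student's (pooled-variance) t-tests, a 1-df chi-squared test of a 1:1
segregation ratio, Tukey's multiple-comparison test after one-way ANOVA, and
box plots whose whiskers extend at most 1.5 × IQR beyond the quartiles
(quartiles by linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError, StatisticsError

__all__ = [
    "BoxStats",
    "ttest_two_tailed",
    "chisq_one_to_one",
    "tukey_groups",
    "box_stats",
]


@dataclass(frozen=True)
class BoxStats:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple


def ttest_two_tailed(a, b, equal_variance: bool = True) -> tuple[float, float]:
    """Two-tailed t-test; Student's pooled-variance by default, Welch optional.

    Degenerate samples (both groups zero-variance) are resolved directly:
    p = 1 when the means are equal, p = 0 when they differ.

    Returns ``(t, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each sample needs >= 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(t), float(p)


def chisq_one_to_one(n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-squared test of counts against an expected 1:1 ratio.

    Used for Mendelian segregation of a resistance marker: expected counts
    are ``(n1+n2)/2`` each.  Returns ``(chi2, p)``.
    """
    if n1 < 0 or n2 < 0:
        raise InputError("counts must be nonnegative")
    if n1 + n2 == 0:
        raise InputError("at least one count must be positive")
    chi2, p = sps.chisquare([n1, n2])
    return float(chi2), float(p)


def tukey_groups(groups: dict) -> dict:
    """Tukey HSD adjusted pairwise p-values across labeled samples.

    ``groups`` maps label -> sample.  With only two groups this reduces to a
    plain t-test (a warning case for the caller); with three or more it is
    the standard one-way-ANOVA-then-Tukey procedure.

    Returns ``{(label_a, label_b): adjusted_p}``.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise StatisticsError("need >= 2 groups")
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise StatisticsError(f"group {lab!r} has < 2 observations")
    if len(samples) == 2:
        _, p = ttest_two_tailed(samples[0], samples[1])
        return {(labels[0], labels[1]): p}
    res = sps.tukey_hsd(*samples)
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    return out


def box_stats(sample) -> BoxStats:
    """Box-plot statistics: median, quartiles, 1.5-IQR whiskers, outliers.

    Quartiles use linear interpolation between order statistics.  Whiskers
    sit at the most extreme data points within 1.5 × IQR of the quartiles
    (never beyond the data range); points outside are listed as outliers.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise InputError("box_stats requires a nonempty sample")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = tuple(sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)]))
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )
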