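"""Model-comparison statistics.

Paired t-tests over per-fold accuracies (or directly from printed summary
statistics), the p-value banding used in comparison tables, and one-way
ANOVA across model groups.  The sample standard deviation uses the n-1
denominator, which is what reproduces published t values from (mean
difference, SD, n) triples: t = mean_diff * sqrt(n) / sd_diff with n-1
degrees of freedom, two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

P_BAND_THRESHOLDS = (0.01, 0.02, 0.10)


def p_band(p: float, thresholds: Sequence[float] = P_BAND_THRESHOLDS) -> str:
    """Band a p-value by the smallest exceeding threshold, else ``>0.10``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    for thr in sorted(thresholds):
        if p < thr:
            return f"<{thr:.2f}"
    return f">{max(thresholds):.2f}"


@dataclass(frozen=True)
class PairedComparison:
    mean_diff: float
    sd_diff: float  # sample SD, n-1 denominator
    n: int
    t: float
    df: int
    p_two_sided: float
    p_band: str
    degenerate: bool = False  # sd_diff == 0 with nonzero mean


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedComparison:
    """Paired t from summary statistics: t = mean_diff * sqrt(n) / sd_diff.

    ``sd_diff == 0`` with a nonzero mean yields an infinite t flagged as
    degenerate (p = 0); zero mean with zero SD gives t = 0, p = 1.
    """
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    if sd_diff < 0:
        raise ValueError("sd_diff must be non-negative")
    df = n - 1
    if sd_diff == 0:
        if mean_diff == 0:
            t, p, degenerate = 0.0, 1.0, False
        else:
            t = np.inf if mean_diff > 0 else -np.inf
            p, degenerate = 0.0, True
    else:
        t = mean_diff * np.sqrt(n) / sd_diff
        p = float(2.0 * sps.t.sf(abs(t), df))
        degenerate = False
    return PairedComparison(
        mean_diff=float(mean_diff), sd_diff=float(sd_diff), n=int(n),
        t=float(t), df=df, p_two_sided=p, p_band=p_band(p), degenerate=degenerate,
    )


def paired_t_from_folds(acc_a: Sequence[float], acc_b: Sequence[float]) -> PairedComparison:
    """Paired t over fold-wise accuracy differences a - b."""
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("fold accuracy vectors must have equal length")
    d = a - b
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return paired_t_from_summary(float(d.mean()), sd, len(d))


def paired_ci(mean_diff: float, sd_diff: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided confidence interval for the mean difference."""
    if n < 2:
        raise ValueError("CI needs n >= 2")
    half = sps.t.ppf(0.5 + level / 2.0, n - 1) * sd_diff / np.sqrt(n)
    return (mean_diff - half, mean_diff + half)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = (SSB/df_b) / (SSW/df_w)."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least two values")
    F, p = sps.f_oneway(*arrays)
    total = sum(len(g) for g in arrays)
    df_between = len(arrays) - 1
    df_within = total - len(arrays)
    if np.isnan(F):  # all groups identical and constant
        F, p = 0.0, 1.0
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=float(p))
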