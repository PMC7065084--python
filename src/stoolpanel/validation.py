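"""Statistics for the immunoassay/FIT validation stage.

Spearman correlation with pairwise missing-value exclusion, and case/control
fold-change with a Wilcoxon rank-sum p-value. Assay concentrations are
skewed and group sizes small, hence rank-based procedures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_used: int


@dataclass
class GroupComparison:
    fold_change: float
    fold_change_median: float
    p_value: float
    n_case: int
    n_control: int
    method: str
    control_mean_zero: bool = False


def spearman_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation on complete pairs (mid-ranks for ties).

    Missing values are excluded pairwise; the p-value uses the t-distribution
    approximation on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:  # a constant argument has no rank ordering
        return CorrelationResult(0.0, 1.0, n)
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n)


def _exact_ranksum_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration over label assignments.

    Valid with ties (mid-ranks); two-sided convention 2 * min(tail), capped
    at 1.
    """
    pooled = np.r_[case, control]
    ranks = stats.rankdata(pooled)
    n1 = len(case)
    obs = float(ranks[:n1].sum())
    sums = np.array(
        [ranks[list(c)].sum() for c in combinations(range(len(pooled)), n1)]
    )
    lo = np.mean(sums <= obs + 1e-12)
    hi = np.mean(sums >= obs - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def group_fold_change(
    values: np.ndarray, groups: np.ndarray, exact_max_n: int = 16
) -> GroupComparison:
    """Case/control fold-change with a two-sided Wilcoxon rank-sum p-value.

    Fold-change is the ratio of group means (medians reported alongside,
    since assay data are skewed). The p-value is exact — full enumeration
    when the pooled size is <= ``exact_max_n`` (valid under ties), the
    classic exact distribution when there are no ties and the smaller group
    has <= 12 observations — and otherwise uses the tie-corrected normal
    approximation.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(bool)
    case = values[groups]
    control = values[~groups]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(values < 0):
        raise ValueError("values must be non-negative")
    mean_ctrl = float(control.mean())
    zero_ctrl = mean_ctrl == 0.0
    fc = float(case.mean()) / (mean_ctrl if not zero_ctrl else np.finfo(float).eps)
    med_ctrl = float(np.median(control))
    fc_med = float(np.median(case)) / (med_ctrl if med_ctrl > 0 else np.finfo(float).eps)

    pooled = np.r_[case, control]
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        p, method = 1.0, "degenerate_all_tied"
    elif len(pooled) <= exact_max_n:
        p, method = _exact_ranksum_p(case, control), "exact_enumeration"
    elif not has_ties and min(len(case), len(control)) <= 12:
        p = float(
            stats.mannwhitneyu(case, control, alternative="two-sided", method="exact").pvalue
        )
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(
                case, control, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
        method = "normal_tie_corrected"
    return GroupComparison(fc, fc_med, p, len(case), len(control), method, zero_ctrl)
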