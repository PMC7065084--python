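"""Cross-validated evaluation of biomarker panels at high specificity.

Population-screening tests must keep the false-positive rate very low, so
panels are judged on the ROC region with specificity between 95% and 100%:
the partial AUC over that band (standardized so 0.5 = chance, 1 = perfect)
and the sensitivity at the cutoff holding specificity at the target. Panels
are compared with a hemoglobin comparator by stratified bootstrap resampling
of case/control individuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lasso import (
    FeatureTransform,
    LassoModel,
    PanelResult,
    PathSpec,
    build_features,
    fit_lasso_logistic,
    lambda_path,
    predict_prob,
    select_panel,
)
from .types import CountMatrix

logger = logging.getLogger("stoolpanel")


def round_pct(x: float) -> int:
    """Round a percentage to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class CVResult:
    sample_ids: list[str]
    prob: np.ndarray  # one cross-validated probability per input sample
    fold_panels: list[list[str]]
    fold_status: list[str]  # "constructed" | "fallback:<size>" | "intercept_only"
    selection_frequency: dict[str, float]


@dataclass
class PaucReport:
    sens: np.ndarray
    spec: np.ndarray
    pauc_raw: float
    pauc_std: float
    sens_at_spec: float
    threshold: float
    confusion: dict[str, int]  # tn, fp, fn, tp
    ci: tuple[float, float]


@dataclass
class BootCompare:
    delta: float
    d_stat: float
    p_value: float
    n_boot: int
    seed: int


@dataclass
class HeldOutResult:
    n_positive: int
    n_total: int
    fraction: float
    ci: tuple[float, float]


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (sensitivity, specificity) at every distinct threshold.

    Ties are grouped (one point per distinct score); the curve starts at
    (sens 0, spec 1) and ends at (sens 1, spec 0). Positive means
    score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(l)[distinct]
    fp = np.cumsum(~l)[distinct]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, (n_neg - fp) / n_neg]
    return sens, spec


def partial_auc(
    sens: np.ndarray,
    spec: np.ndarray,
    spec_lo: float = 0.95,
    spec_hi: float = 1.0,
) -> tuple[float, float]:
    """Partial area under the ROC curve over a specificity band.

    Trapezoidal integration of sensitivity over specificity in
    [spec_lo, spec_hi], linearly interpolating at the band edges. The
    standardized value rescales the raw area so that a chance-level
    classifier scores 0.5 and a perfect one scores 1:

        pauc_std = 0.5 * (1 + (raw - A_chance) / (A_max - A_chance))

    with A_max the band width and A_chance the diagonal's area in the band.
    """
    if spec_lo >= spec_hi:
        raise ValueError("need spec_lo < spec_hi")
    fpr = 1.0 - np.asarray(spec, dtype=float)
    sens = np.asarray(sens, dtype=float)
    order = np.lexsort((sens, fpr))
    fpr, sens = fpr[order], sens[order]
    lo, hi = 1.0 - spec_hi, 1.0 - spec_lo
    # trapezoids over the segments clipped to the band; vertical jumps
    # (tied fpr) contribute nothing
    raw = 0.0
    for i in range(1, len(fpr)):
        x0, x1, y0, y1 = fpr[i - 1], fpr[i], sens[i - 1], sens[i]
        if x1 <= lo or x0 >= hi or x1 == x0:
            continue
        xa, xb = max(x0, lo), min(x1, hi)
        ya = y0 + (y1 - y0) * (xa - x0) / (x1 - x0)
        yb = y0 + (y1 - y0) * (xb - x0) / (x1 - x0)
        raw += (xb - xa) * (ya + yb) / 2.0
    width = spec_hi - spec_lo
    a_chance = width**2 / 2.0 + width * (1.0 - spec_hi)
    std = 0.5 * (1.0 + (raw - a_chance) / (width - a_chance))
    return raw, float(std)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval from beta quantiles."""
    if not (0 <= x <= n and n >= 1):
        raise ValueError(f"invalid x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def sensitivity_at_specificity(
    scores: np.ndarray,
    labels: np.ndarray,
    spec_target: float = 0.95,
    ci_level: float = 0.95,
) -> PaucReport:
    """Confusion matrix and sensitivity at the high-specificity cutoff.

    The cutoff is the smallest score value that, used as a >= threshold,
    keeps the number of false-positive controls at or below
    floor((1 - spec_target) * n_controls); with no admissible value (mass
    ties) nothing is called positive. An exact Clopper-Pearson CI is attached
    to the sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    allowed_fp = math.floor((1.0 - spec_target) * n_neg)
    threshold = math.inf
    for t in np.unique(scores):  # ascending: smallest admissible cutoff wins
        fp = int(np.sum((scores >= t) & ~labels))
        if fp <= allowed_fp:
            threshold = float(t)
            break
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = n_pos - tp
    tn = n_neg - fp
    sens_val = tp / n_pos
    sens, spec = roc_curve(scores, labels)
    raw, std = partial_auc(sens, spec, spec_target, 1.0)
    return PaucReport(
        sens=sens,
        spec=spec,
        pauc_raw=raw,
        pauc_std=std,
        sens_at_spec=sens_val,
        threshold=threshold,
        confusion={"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        ci=clopper_pearson(tp, n_pos, ci_level),
    )


def compare_pauc_bootstrap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    spec_lo: float = 0.95,
    spec_hi: float = 1.0,
) -> BootCompare:
    """Stratified bootstrap comparison of two paired score vectors.

    Cases and controls are resampled with replacement separately; the
    standardized pAUC difference is recomputed per replicate. The observed
    difference divided by the bootstrap SD is referred to the standard
    normal (two-sided).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("score vectors and labels must be paired and equal-length")

    def _pstd(s: np.ndarray, l: np.ndarray) -> float:
        sens, spec = roc_curve(s, l)
        return partial_auc(sens, spec, spec_lo, spec_hi)[1]

    delta = _pstd(scores_a, labels) - _pstd(scores_b, labels)
    if np.array_equal(scores_a, scores_b):
        return BootCompare(0.0, 0.0, 1.0, n_boot, seed)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels)
    ctrl_idx = np.flatnonzero(~labels)
    deltas = np.empty(n_boot)
    boot_labels = np.r_[np.ones(len(case_idx), bool), np.zeros(len(ctrl_idx), bool)]
    for b in range(n_boot):
        idx = np.r_[
            rng.choice(case_idx, len(case_idx), replace=True),
            rng.choice(ctrl_idx, len(ctrl_idx), replace=True),
        ]
        deltas[b] = _pstd(scores_a[idx], boot_labels) - _pstd(scores_b[idx], boot_labels)
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        if delta != 0.0:
            logger.warning("zero bootstrap SD with non-zero delta; reporting p=0")
            return BootCompare(float(delta), math.inf, 0.0, n_boot, seed)
        return BootCompare(0.0, 0.0, 1.0, n_boot, seed)
    d = float(delta) / sd
    p = float(2.0 * stats.norm.sf(abs(d)))
    return BootCompare(float(delta), d, p, n_boot, seed)


def apply_to_held_out(threshold: float, scores: np.ndarray, ci_level: float = 0.95) -> HeldOutResult:
    """Classify a held-out class at a previously fixed cutoff."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty held-out set")
    n_pos = int(np.sum(scores >= threshold))
    n = len(scores)
    return HeldOutResult(n_pos, n, n_pos / n, clopper_pearson(n_pos, n, ci_level))


def loocv_predict(
    m: CountMatrix,
    labels: np.ndarray,
    candidates: list[str],
    k: int,
    path_spec: PathSpec = PathSpec(),
) -> CVResult:
    """Leave-one-out cross-validated panel probabilities.

    The candidate list is fixed in advance (computed once on the full data,
    mirroring the discovery workflow — the induced optimism is noted in the
    run report). Within each fold, normalization, standardization and panel
    selection are recomputed without the held-out sample. Folds where the
    size-k panel is not constructible fall back to the largest constructed
    size below k on that fold's path (never larger); the fallback is
    recorded.
    """
    labels = np.asarray(labels).astype(int)
    n = m.n_samples
    if labels.shape != (n,):
        raise ValueError("labels must align with samples")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need >=2 cases and >=2 controls")
    probs = np.empty(n)
    fold_panels: list[list[str]] = []
    fold_status: list[str] = []
    for i in range(n):
        train_idx = np.r_[0:i, i + 1 : n]
        m_train = m.subset_samples(train_idx)
        y_train = labels[train_idx]
        X_train, tf = build_features(m_train, candidates)
        panel = select_panel(X_train, y_train, k, path_spec, tf.feature_names)
        if panel.status == "constructed":
            model = panel.model
            status = "constructed"
        else:
            model, size = _fallback_model(X_train, y_train, k, path_spec, tf)
            status = f"fallback:{size}" if model.n_selected > 0 else "intercept_only"
        X_test = tf.apply(m.subset_samples([i]))
        probs[i] = float(predict_prob(model, X_test)[0])
        fold_panels.append(model.selected)
        fold_status.append(status)
    freq = {
        c: float(np.mean([c in panel for panel in fold_panels])) for c in candidates
    }
    return CVResult(list(m.sample_ids), probs, fold_panels, fold_status, freq)


def _fallback_model(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    path_spec: PathSpec,
    tf: FeatureTransform,
) -> tuple[LassoModel, int]:
    models = lambda_path(
        X, y, path_spec.n_lambda, path_spec.lambda_min_ratio, tf.feature_names,
        stop_at_size=k,
    )
    best = models[0]  # null model at lambda_max
    for mod in models:
        if best.n_selected < mod.n_selected < k:
            best = mod
    return best, best.n_selected
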