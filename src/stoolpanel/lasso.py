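"""L1-penalized logistic regression and fixed-size biomarker-panel selection.

The model minimizes (1/n) * logistic negative log-likelihood + lambda * ||beta||_1
with an unpenalized intercept, solved by cyclic coordinate descent on the
iteratively reweighted quadratic approximation (glmnet-style). Panels of a
requested size k are found by walking a geometric lambda path from sparse to
dense and taking the first model with exactly k non-zero coefficients; when
the active set jumps past k (correlated markers entering or leaving together)
the bracketing interval is refined once before the size is declared not
constructible — the same phenomenon by which a 4-protein panel can exist
while the 3- and 2-protein panels do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .diffabund import normalize_counts
from .types import CountMatrix

logger = logging.getLogger("stoolpanel")


@dataclass
class FeatureTransform:
    """Feature construction recipe fitted on training samples.

    Features are log2(normalized count + 1), centered and unit-scaled with
    the training mean/scale. Constant training features are dropped.
    """

    candidates: list[str]
    median_total: float
    center: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # boolean over candidates

    @property
    def feature_names(self) -> list[str]:
        return [c for c, k in zip(self.candidates, self.kept) if k]

    def apply(self, m: CountMatrix) -> np.ndarray:
        """Transform new samples with the stored standardization."""
        idx = [m.protein_index(c) for c in self.candidates]
        totals = m.totals.astype(float)
        if np.any(totals == 0):
            raise ValueError("zero-total sample in transform input")
        norm = m.counts[idx, :] / totals * self.median_total
        X = np.log2(norm + 1.0).T
        X = (X[:, self.kept] - self.center) / self.scale
        return X


def build_features(
    m: CountMatrix, candidates: list[str]
) -> tuple[np.ndarray, FeatureTransform]:
    """Build the standardized feature matrix for the candidate proteins."""
    if not candidates:
        raise ValueError("empty candidate list")
    idx = [m.protein_index(c) for c in candidates]  # raises on unknown id
    norm = normalize_counts(m)[idx, :]
    X_full = np.log2(norm + 1.0).T  # samples x candidates
    center = X_full.mean(axis=0)
    scale = X_full.std(axis=0)  # population scaling
    kept = scale > 0
    if not kept.all():
        dropped = [c for c, k in zip(candidates, kept) if not k]
        logger.warning("dropping constant features: %s", dropped)
    tf = FeatureTransform(
        list(candidates), float(np.median(m.totals)), center[kept], scale[kept], kept
    )
    X = (X_full[:, kept] - center[kept]) / scale[kept]
    return X, tf


@dataclass
class LassoModel:
    intercept: float
    coef: np.ndarray
    lam: float
    feature_names: list[str]
    transform: FeatureTransform | None = None

    @property
    def selected(self) -> list[str]:
        return [f for f, b in zip(self.feature_names, self.coef) if b != 0.0]

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))


@dataclass
class PathSpec:
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    refine_points: int = 25


@dataclass
class PanelResult:
    requested_size: int
    status: str  # "constructed" | "not_constructible"
    model: LassoModel | None
    size_sequence: list[int]


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda for which the all-zero coefficient vector is optimal."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_names: list[str] | None = None,
    warm: tuple[float, np.ndarray] | None = None,
    tol: float = 1e-9,
    kkt_tol: float = 1e-8,
    max_outer: int = 200,
) -> LassoModel:
    """Fit the L1-penalized logistic model at one penalty value.

    Cyclic coordinate descent on the weighted quadratic approximation,
    re-linearized until the exact KKT conditions hold at ``kkt_tol``:
    for zero coefficients |(1/n) x_j'(y - p)| <= lambda, for non-zero ones
    (1/n) x_j'(y - p) = lambda * sign(beta_j).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes, coded 0/1")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    if warm is not None:
        beta0, beta = warm[0], warm[1].copy()
    else:
        beta0, beta = float(logit(y.mean())), np.zeros(p)

    eta = beta0 + X @ beta
    for _ in range(max_outer):
        prob = expit(eta)
        w = np.clip(prob * (1 - prob), 1e-6, None)
        z = eta + (y - prob) / w
        wx2 = (w[:, None] * X**2).mean(axis=0)
        r = z - eta  # working residual at current coefficients
        # inner cyclic coordinate descent on the fixed quadratic
        for _ in range(200):
            max_delta = 0.0
            d0 = float(np.sum(w * r) / np.sum(w))
            if d0 != 0.0:
                beta0 += d0
                r -= d0
                max_delta = abs(d0)
            for j in range(p):
                bj = beta[j]
                zj = float((w * X[:, j]) @ r) / n + wx2[j] * bj
                new = _soft(zj, lam) / wx2[j]
                if new != bj:
                    r -= X[:, j] * (new - bj)
                    beta[j] = new
                    max_delta = max(max_delta, abs(new - bj))
            if max_delta < tol:
                break
        eta_new = beta0 + X @ beta
        # exact KKT check at the re-linearization point
        g = X.T @ (y - expit(eta_new)) / n
        viol = 0.0
        for j in range(p):
            if beta[j] == 0.0:
                viol = max(viol, abs(g[j]) - lam)
            else:
                viol = max(viol, abs(g[j] - lam * np.sign(beta[j])))
        if float(np.max(np.abs(eta_new - eta))) < tol and viol <= kkt_tol:
            eta = eta_new
            break
        eta = eta_new
    beta[np.abs(beta) < 1e-12] = 0.0  # drop tie-break numerical dust
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(p)]
    return LassoModel(beta0, beta, float(lam), list(names))


def kkt_residual(X: np.ndarray, y: np.ndarray, model: LassoModel) -> float:
    """Max violation of the subgradient optimality conditions."""
    n = len(y)
    prob = expit(model.intercept + X @ model.coef)
    g = X.T @ (y - prob) / n
    viol = abs(float(np.mean(y - prob)))  # unpenalized intercept
    for j in range(X.shape[1]):
        if model.coef[j] == 0.0:
            viol = max(viol, abs(g[j]) - model.lam)
        else:
            viol = max(viol, abs(g[j] - model.lam * np.sign(model.coef[j])))
    return max(viol, 0.0)


#: Looser convergence for warm-started path points; panel membership (which
#: coefficients are non-zero) is insensitive to the final digits, and the
#: path would otherwise crawl on quasi-separable leave-one-out folds.
_PATH_TOL = 1e-7
_PATH_MAX_OUTER = 40


def path_lambdas(
    X: np.ndarray, y: np.ndarray, n_lambda: int, lambda_min_ratio: float
) -> np.ndarray:
    lmax = lambda_max(X, y)
    return lmax * lambda_min_ratio ** (np.arange(n_lambda) / (n_lambda - 1))


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    feature_names: list[str] | None = None,
    stop_at_size: int | None = None,
) -> list[LassoModel]:
    """Warm-started fits on a geometric grid from lambda_max downwards.

    With ``stop_at_size`` the walk ends at the first model selecting at
    least that many features (the rest of the path is irrelevant for
    panel-size search).
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    models = []
    warm = None
    for lam in path_lambdas(X, y, n_lambda, lambda_min_ratio):
        m = fit_lasso_logistic(
            X, y, float(lam), feature_names, warm=warm,
            tol=_PATH_TOL, kkt_tol=1e-6, max_outer=_PATH_MAX_OUTER,
        )
        warm = (m.intercept, m.coef)
        models.append(m)
        if stop_at_size is not None and m.n_selected >= stop_at_size:
            break
    return models


def select_panel(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    path_spec: PathSpec = PathSpec(),
    feature_names: list[str] | None = None,
) -> PanelResult:
    """Return the first model of exactly k features along the lambda path.

    If the active-set size jumps past k between neighbouring grid points, the
    bracketing lambda interval is refined once with a finer geometric grid;
    if k still never occurs the panel is reported as not constructible, with
    the observed size sequence.
    """
    if k < 1:
        raise ValueError("panel size k must be >= 1")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds number of candidates {X.shape[1]}")
    models = lambda_path(
        X, y, path_spec.n_lambda, path_spec.lambda_min_ratio, feature_names,
        stop_at_size=k,
    )
    sizes = [m.n_selected for m in models]
    if sizes[-1] == k:
        return PanelResult(k, "constructed", models[-1], sizes)
    # one local refinement between the lambdas bracketing the jump past k
    if len(models) >= 2 and sizes[-2] < k < sizes[-1]:
        hi, lo = models[-2].lam, models[-1].lam
        grid = np.geomspace(hi, lo, path_spec.refine_points)
        warm = (models[-2].intercept, models[-2].coef)
        for lam in grid:
            m = fit_lasso_logistic(
                X, y, float(lam), feature_names, warm=warm,
                tol=_PATH_TOL, kkt_tol=1e-6, max_outer=_PATH_MAX_OUTER,
            )
            warm = (m.intercept, m.coef)
            if m.n_selected == k:
                return PanelResult(k, "constructed", m, sizes)
    return PanelResult(k, "not_constructible", None, sizes)


def predict_prob(model: LassoModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted case probabilities sigmoid(beta0 + X beta) for transformed X."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.coef):
        raise ValueError(
            f"feature mismatch: model has {len(model.coef)}, input has {X_new.shape[1]}"
        )
    return expit(model.intercept + X_new @ model.coef)
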