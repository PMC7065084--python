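"""Differential abundance of spectral counts via a beta-binomial model.

Each protein's count in a sample is modelled as the number of spectra
(out of the sample's total) that land on that protein: y ~ BetaBinomial(n,
alpha, beta) with mean proportion pi and overdispersion phi, parameterized as

    alpha = pi (1 - phi) / phi,   beta = (1 - pi)(1 - phi) / phi,

so Var(y/n) = pi(1-pi)(phi + (1-phi)/n) and phi -> 0 recovers the binomial.
Case/control differences are tested with a likelihood-ratio test: the null
fits a common pi (shared phi), the alternative one pi per group (phi still
shared, so the statistic has one degree of freedom and is referred to
chi-square(1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix

_PHI_BINOMIAL = 1e-8  # below this, evaluate the binomial limit directly
_PI_EPS = 1e-9


@dataclass
class BetaBinomFit:
    """Maximum-likelihood fit of the beta-binomial model.

    ``pi`` has one entry per group (one entry when fit without groups);
    ``phi`` is shared.
    """

    pi: np.ndarray
    phi: float
    loglik: float
    flagged: bool = False  # degenerate input (e.g. all-zero protein)


@dataclass
class DEResult:
    protein_id: str
    log2fc: float
    p_raw: float
    p_adj: float | None
    direction: str  # "up" | "down" | "none"


def normalize_counts(m: CountMatrix) -> np.ndarray:
    """Normalized spectral counts: counts / sample total x median total."""
    totals = m.totals
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-total sample: {m.sample_ids[zero[0]]!r}")
    return m.counts / totals * np.median(totals)


def betabinom_loglik(
    y: np.ndarray, n: np.ndarray, pi: float, phi: float
) -> float:
    """Log-likelihood of counts y out of totals n under BetaBinomial(pi, phi).

    At phi = 0 this is the binomial log-likelihood (continuity limit).
    Samples with n = 0 (and hence y = 0) contribute zero.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(y > n) or np.any(y < 0):
        raise ValueError("need 0 <= y <= n elementwise")
    if not 0 < pi < 1:
        raise ValueError("need 0 < pi < 1")
    if phi < 0:
        raise ValueError("need phi >= 0")
    choose = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    if phi < _PHI_BINOMIAL:
        ll = choose + y * math.log(pi) + (n - y) * math.log1p(-pi)
    else:
        a = pi * (1 - phi) / phi
        b = (1 - pi) * (1 - phi) / phi
        ll = choose + special.betaln(y + a, n - y + b) - special.betaln(a, b)
    return float(ll.sum())


def _group_loglik(
    y: np.ndarray, n: np.ndarray, groups: np.ndarray, pis: np.ndarray, phi: float
) -> float:
    total = 0.0
    for g, pi in enumerate(pis):
        mask = groups == g
        total += betabinom_loglik(y[mask], n[mask], pi, phi)
    return total


def _smoothed_pi(y: np.ndarray, n: np.ndarray) -> float:
    """(sum y + 0.5) / (sum n + 1): keeps fold-changes finite at zero counts."""
    return (float(np.sum(y)) + 0.5) / (float(np.sum(n)) + 1.0)


def fit_betabinom(
    y: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray | None = None,
) -> BetaBinomFit:
    """Maximum-likelihood (pi per group, shared phi) by bounded optimization.

    Deterministic: a method-of-moments start plus one fallback start at the
    pooled proportion with phi = 0.01; the better optimum wins. An all-zero
    protein is returned at the smoothed proportion and flagged.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
    else:
        groups = np.asarray(groups, dtype=int)
    n_groups = int(groups.max()) + 1
    for g in range(n_groups):
        if (groups == g).sum() < 2:
            raise ValueError("need >=2 samples per group")

    if np.sum(y) == 0:
        pis = np.array([_smoothed_pi(y[groups == g], n[groups == g])
                        for g in range(n_groups)])
        ll = _group_loglik(y, n, groups, pis, 0.0)
        return BetaBinomFit(pis, 0.0, ll, flagged=True)

    pooled = float(np.clip(np.sum(y) / np.sum(n), _PI_EPS, 1 - _PI_EPS))
    mom = np.array(
        [np.clip(_smoothed_pi(y[groups == g], n[groups == g]), _PI_EPS, 1 - _PI_EPS)
         for g in range(n_groups)]
    )
    # crude moment start for phi from the excess variance of per-sample rates
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n > 0, y / np.maximum(n, 1), pooled)
    excess = max(float(np.var(rate)) - pooled * (1 - pooled) / max(float(np.mean(n)), 1.0), 0.0)
    phi_mom = float(np.clip(excess / max(pooled * (1 - pooled), 1e-12), 1e-4, 0.5))

    bounds = [(_PI_EPS, 1 - 1e-6)] * n_groups + [(0.0, 0.995)]

    def nll(params: np.ndarray) -> float:
        pis, phi = params[:-1], params[-1]
        return -_group_loglik(y, n, groups, pis, phi)

    best = None
    for start in (np.append(mom, phi_mom), np.append(np.full(n_groups, pooled), 0.01)):
        res = optimize.minimize(
            nll, start, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    pis = np.clip(best.x[:-1], _PI_EPS, 1 - 1e-6)
    phi = float(best.x[-1])
    return BetaBinomFit(pis, phi, -float(best.fun))


def betabinom_test(
    y: np.ndarray, n: np.ndarray, groups: np.ndarray, protein_id: str = ""
) -> DEResult:
    """Beta-binomial likelihood-ratio test of a case/control difference.

    ``groups`` is binary (0 = control, 1 = case). The two-sided p comes from
    referring 2(l_alt - l_null) to chi-square(1); the log2 fold-change is the
    ratio of smoothed group proportions and carries the direction.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    groups = np.asarray(groups, dtype=int)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be binary 0/1")
    if (groups == 0).sum() < 2 or (groups == 1).sum() < 2:
        raise ValueError("need >=2 samples in each group")

    null = fit_betabinom(y, n, None)
    if np.sum(y) == 0:
        # no information: identical groups by construction
        return DEResult(protein_id, 0.0, 1.0, None, "none")
    # alternative: start from the null solution (guarantees l_alt >= l_null)
    # and from group-wise moments
    alt = _fit_alt(y, n, groups, null)
    stat = max(0.0, 2.0 * (alt.loglik - null.loglik))
    p_raw = float(stats.chi2.sf(stat, df=1))
    pi0 = _smoothed_pi(y[groups == 0], n[groups == 0])
    pi1 = _smoothed_pi(y[groups == 1], n[groups == 1])
    log2fc = math.log2(pi1 / pi0)
    if log2fc > 0:
        direction = "up"
    elif log2fc < 0:
        direction = "down"
    else:
        direction = "none"
    return DEResult(protein_id, log2fc, p_raw, None, direction)


def _fit_alt(
    y: np.ndarray, n: np.ndarray, groups: np.ndarray, null: BetaBinomFit
) -> BetaBinomFit:
    bounds = [(_PI_EPS, 1 - 1e-6)] * 2 + [(0.0, 0.995)]

    def nll(params: np.ndarray) -> float:
        return -_group_loglik(y, n, groups, params[:2], params[2])

    mom = np.array(
        [np.clip(_smoothed_pi(y[groups == g], n[groups == g]), _PI_EPS, 1 - 1e-6)
         for g in (0, 1)]
    )
    starts = [
        np.array([null.pi[0], null.pi[0], null.phi]),
        np.append(mom, max(null.phi, 1e-4)),
    ]
    best = None
    for start in starts:
        res = optimize.minimize(
            nll, start, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    loglik = -float(best.fun)
    # the null is nested in the alternative; never report a worse optimum
    loglik = max(loglik, null.loglik)
    return BetaBinomFit(np.clip(best.x[:2], _PI_EPS, 1 - 1e-6), float(best.x[2]), loglik)


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, order-preserving. Default Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mapping = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}
    if method not in mapping:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=mapping[method])[1]


def de_table(
    m: CountMatrix,
    case_mask: np.ndarray,
    adjust_method: str = "bh",
) -> pd.DataFrame:
    """Run the beta-binomial test for every protein; attach adjusted p-values.

    ``case_mask`` is boolean over samples (True = case). Returns a DataFrame
    with columns protein_id, log2fc, p_raw, p_adj, direction, in matrix order.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    groups = case_mask.astype(int)
    totals = m.totals
    rows = []
    for i, pid in enumerate(m.protein_ids):
        r = betabinom_test(m.counts[i], totals, groups, pid)
        rows.append({"protein_id": pid, "log2fc": r.log2fc, "p_raw": r.p_raw,
                     "direction": r.direction})
    df = pd.DataFrame(rows)
    df["p_adj"] = adjust_pvalues(df["p_raw"].to_numpy(), adjust_method)
    return df[["protein_id", "log2fc", "p_raw", "p_adj", "direction"]]


def select_candidates(
    results: pd.DataFrame,
    fc_min: float,
    p_max: float,
    use_adjusted: bool,
    strict_fc: bool,
) -> list[str]:
    """Select upregulated candidate proteins under one of the two regimes.

    Loose regime (``strict_fc=False``): strictly positive log2 fold-change and
    raw p <= p_max. Strict regime (``strict_fc=True``): log2 fold-change >=
    fc_min and (adjusted) p <= p_max. Returned ids are sorted by p then by
    descending fold-change.
    """
    if results.empty:
        return []
    p = results["p_adj"] if use_adjusted else results["p_raw"]
    fc = results["log2fc"]
    if strict_fc:
        keep = (fc >= fc_min) & (p <= p_max)
    else:
        keep = (fc > fc_min) & (p <= p_max)
    sub = results.loc[keep].copy()
    sub["_p"] = p[keep]
    sub = sub.sort_values(["_p", "log2fc"], ascending=[True, False])
    return sub["protein_id"].tolist()


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of a list overlap.

    X counts the overlap of a random size-``n`` subset with a fixed size-``K``
    subset of a universe of ``N``. Computed by log-sum-exp over log pmf terms.
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise ValueError(f"inconsistent sizes k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1, dtype=float)
    logpmf = (
        special.gammaln(K + 1) - special.gammaln(i + 1) - special.gammaln(K - i + 1)
        + special.gammaln(N - K + 1) - special.gammaln(n - i + 1)
        - special.gammaln(N - K - n + i + 1)
        - (special.gammaln(N + 1) - special.gammaln(n + 1) - special.gammaln(N - n + 1))
    )
    return float(min(1.0, math.exp(special.logsumexp(logpmf))))
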