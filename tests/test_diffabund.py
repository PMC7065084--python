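import itertools

import numpy as np
import pytest
from scipy import optimize, special, stats

from stoolpanel import diffabund
from stoolpanel.types import CountMatrix


class TestNormalize:
    def test_equal_totals_identity(self):
        m = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[3, 4], [7, 6]]))
        np.testing.assert_allclose(diffabund.normalize_counts(m), m.counts)

    def test_scale_invariance_of_one_sample(self):
        m1 = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[2, 4], [8, 6]]))
        m2 = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[4, 4], [16, 6]]))
        n1 = diffabund.normalize_counts(m1)
        n2 = diffabund.normalize_counts(m2)
        np.testing.assert_allclose(n1[:, 0] / n1[:, 0].sum(), n2[:, 0] / n2[:, 0].sum())

    def test_hand_computed_two_by_two(self):
        # totals 100 and 200, median 150
        m = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[10, 50], [90, 150]]))
        out = diffabund.normalize_counts(m)
        np.testing.assert_allclose(out, [[15.0, 37.5], [135.0, 112.5]])

    def test_zero_total_sample_named(self):
        m = CountMatrix(["a"], ["s1", "s2"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="s2"):
            diffabund.normalize_counts(m)


class TestLoglik:
    def test_phi_zero_equals_binomial(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(1, 50, size=10)
            y = rng.binomial(n, 0.3)
            pi = rng.uniform(0.05, 0.95)
            ours = diffabund.betabinom_loglik(y, n, pi, 0.0)
            ref = stats.binom.logpmf(y, n, pi).sum()
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_matches_scipy_betabinom(self):
        y = np.array([0, 3, 7, 2])
        n = np.array([10, 10, 20, 5])
        pi, phi = 0.3, 0.1
        a = pi * (1 - phi) / phi
        b = (1 - pi) * (1 - phi) / phi
        ref = stats.betabinom.logpmf(y, n, a, b).sum()
        assert diffabund.betabinom_loglik(y, n, pi, phi) == pytest.approx(ref, rel=1e-10)

    def test_empty_trials_contribute_zero(self):
        base = diffabund.betabinom_loglik(np.array([3]), np.array([10]), 0.3, 0.05)
        padded = diffabund.betabinom_loglik(
            np.array([3, 0]), np.array([10, 0]), 0.3, 0.05
        )
        assert padded == pytest.approx(base, abs=1e-12)

    def test_y_above_n_rejected(self):
        with pytest.raises(ValueError):
            diffabund.betabinom_loglik(np.array([5]), np.array([3]), 0.3, 0.1)


def _simulate(pi, phi, n, rng):
    if phi == 0:
        return rng.binomial(n, pi)
    a = pi * (1 - phi) / phi
    b = (1 - pi) * (1 - phi) / phi
    return rng.binomial(n, rng.beta(a, b, size=len(n)))


class TestFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = rng.lognormal(np.log(1000), 0.2, 200).astype(int)
        y = _simulate(0.05, 0.02, n, rng)
        fit = diffabund.fit_betabinom(y, n)
        assert fit.pi[0] == pytest.approx(0.05, abs=0.01)
        assert fit.phi == pytest.approx(0.02, abs=0.01)

    def test_binomial_boundary_recovery(self):
        rng = np.random.default_rng(2)
        n = np.full(300, 2000)
        y = _simulate(0.05, 0.0, n, rng)
        fit = diffabund.fit_betabinom(y, n)
        assert fit.phi <= 0.005

    def test_identical_groups_get_equal_pi(self):
        y = np.array([3, 5, 3, 5])
        n = np.array([100, 100, 100, 100])
        fit = diffabund.fit_betabinom(y, n, groups=np.array([0, 0, 1, 1]))
        assert fit.pi[0] == pytest.approx(fit.pi[1], rel=1e-4)

    def test_all_zero_protein_flagged(self):
        fit = diffabund.fit_betabinom(
            np.zeros(6, int), np.full(6, 100), groups=np.array([0, 0, 0, 1, 1, 1])
        )
        assert fit.flagged


def _binomial_lrt_oracle(y, n, groups):
    """Brute-force binomial likelihood-ratio test (independent oracle)."""

    def best_ll(yy, nn):
        res = optimize.minimize_scalar(
            lambda p: -stats.binom.logpmf(yy, nn, p).sum(),
            bounds=(1e-9, 1 - 1e-9),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    ll_null = best_ll(y, n)
    ll_alt = best_ll(y[groups == 0], n[groups == 0]) + best_ll(
        y[groups == 1], n[groups == 1]
    )
    stat = max(0.0, 2 * (ll_alt - ll_null))
    return stats.chi2.sf(stat, 1)


class TestBetabinomTest:
    def test_identical_groups_are_null(self):
        y = np.array([3, 5, 3, 5])
        n = np.array([100, 100, 100, 100])
        r = diffabund.betabinom_test(y, n, np.array([0, 0, 1, 1]))
        assert r.log2fc == 0.0
        assert r.p_raw > 0.9

    def test_matches_binomial_lrt_oracle_at_large_n(self):
        rng = np.random.default_rng(3)
        groups = np.r_[np.zeros(20, int), np.ones(20, int)]
        n = np.full(40, 5000)
        y = np.r_[rng.binomial(5000, 0.01, 20), rng.binomial(5000, 0.013, 20)]
        ours = diffabund.betabinom_test(y, n, groups)
        oracle = _binomial_lrt_oracle(y, n, groups)
        # phi is estimated near 0, so the LRT should match the binomial one
        assert ours.p_raw == pytest.approx(oracle, rel=0.05, abs=1e-4)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(4)
        groups = np.r_[np.zeros(25, int), np.ones(25, int)]
        power = []
        for fc in (1.0, 2.0, 4.0):
            rejections = 0
            for _ in range(40):
                n = rng.lognormal(np.log(2000), 0.2, 50).astype(int)
                y0 = _simulate(0.005, 0.01, n[:25], rng)
                y1 = _simulate(min(0.005 * fc, 0.5), 0.01, n[25:], rng)
                r = diffabund.betabinom_test(np.r_[y0, y1], n, groups)
                rejections += r.p_raw <= 0.05
            power.append(rejections / 40)
        assert power[0] <= power[1] <= power[2] or (power[1] > 0.9 and power[2] > 0.9)
        assert power[2] > power[0]

    def test_direction_follows_fold_change(self):
        rng = np.random.default_rng(5)
        n = np.full(20, 3000)
        groups = np.r_[np.zeros(10, int), np.ones(10, int)]
        y = np.r_[rng.binomial(3000, 0.002, 10), rng.binomial(3000, 0.02, 10)]
        r = diffabund.betabinom_test(y, n, groups)
        assert r.direction == "up" and r.log2fc > 0


class TestAdjustAndSelect:
    def test_bh_hand_example(self):
        out = diffabund.adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert diffabund.adjust_pvalues(np.array([0.37]))[0] == pytest.approx(0.37)
        np.testing.assert_allclose(diffabund.adjust_pvalues(np.ones(5)), 1.0)

    def test_adjusted_at_least_raw_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=30)
        adj = diffabund.adjust_pvalues(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(30)
        np.testing.assert_allclose(diffabund.adjust_pvalues(p[perm]), adj[perm])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            diffabund.adjust_pvalues(np.array([0.5, 1.2]))

    def test_select_candidates_regimes(self):
        import pandas as pd
        table = pd.DataFrame(
            {
                "protein_id": ["A", "B", "C"],
                "log2fc": [2.5, 0.5, -1.0],
                "p_raw": [0.01, 0.08, 0.001],
                "p_adj": [0.04, 0.2, 0.004],
                "direction": ["up", "up", "down"],
            }
        )
        loose = diffabund.select_candidates(table, 0.0, 0.1, False, False)
        assert set(loose) == {"A", "B"}
        strict = diffabund.select_candidates(table, 2.0, 0.05, True, True)
        assert strict == ["A"]
        assert diffabund.select_candidates(table.iloc[:0], 0, 0.1, False, False) == []


class TestHypergeom:
    def test_zero_overlap_certain(self):
        assert diffabund.hypergeom_overlap(0, 5, 5, 10) == 1.0

    def test_direct_enumeration_value(self):
        assert diffabund.hypergeom_overlap(5, 5, 5, 10) == pytest.approx(
            1 / 252, rel=1e-12
        )

    def test_full_universe_forces_overlap(self):
        assert diffabund.hypergeom_overlap(3, 10, 3, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in (8, 12, 15):
            universe = range(N)
            for K, n in [(3, 4), (5, 5), (N // 2, N // 3)]:
                fixed = set(range(K))
                for k in range(0, min(K, n) + 1):
                    count = sum(
                        1
                        for sub in itertools.combinations(universe, n)
                        if len(fixed & set(sub)) >= k
                    )
                    expected = count / special.comb(N, n, exact=True)
                    got = diffabund.hypergeom_overlap(k, K, n, N)
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            diffabund.hypergeom_overlap(6, 5, 5, 10)
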