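import numpy as np
import pytest
from scipy import stats

from stoolpanel import evaluate, lasso
from stoolpanel.evaluate import (
    apply_to_held_out,
    clopper_pearson,
    compare_pauc_bootstrap,
    loocv_predict,
    partial_auc,
    roc_curve,
    round_pct,
    sensitivity_at_specificity,
)
from stoolpanel.simulate import CohortDesign, generate_cohort


def brute_force_roc(scores, labels):
    """Independent oracle: enumerate every distinct threshold directly."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    points = [(0.0, 1.0)]
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        sens = np.mean(pred[labels])
        spec = np.mean(~pred[~labels])
        points.append((sens, spec))
    return points


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        scores = np.r_[np.zeros(8), np.ones(4)]
        labels = scores > 0
        sens, spec = roc_curve(scores, labels)
        assert any(s == 1.0 and sp == 1.0 for s, sp in zip(sens, spec))

    def test_all_tied_scores_two_point_diagonal(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        sens, spec = roc_curve(np.ones(10), labels)
        assert sens.tolist() == [0.0, 1.0]
        assert spec.tolist() == [1.0, 0.0]

    def test_four_observation_toy_matches_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.95])
        labels = np.array([True, True, False, False])
        sens, spec = roc_curve(scores, labels)
        expected = brute_force_roc(scores, labels)
        assert list(zip(sens, spec)) == expected

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 21)
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.8], size=n)  # force ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        sens, spec = roc_curve(scores, labels)
        assert list(zip(sens, spec)) == brute_force_roc(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.arange(4.0), np.ones(4, bool))


class TestPartialAuc:
    def test_perfect_classifier(self):
        scores = np.r_[np.zeros(40), np.ones(10)]
        sens, spec = roc_curve(scores, scores > 0)
        raw, std = partial_auc(sens, spec)
        assert raw == pytest.approx(0.05, abs=1e-12)
        assert std == pytest.approx(1.0, abs=1e-12)

    def test_tie_degenerate_diagonal_is_chance(self):
        labels = np.r_[np.zeros(30), np.ones(10)].astype(bool)
        sens, spec = roc_curve(np.ones(40), labels)
        _, std = partial_auc(sens, spec)
        assert std == pytest.approx(0.5, abs=1e-12)

    def test_hand_integrated_staircase(self):
        # trapezoids over fpr in [0, 0.05]: segment (0,0)->(0.02,0.2) gives
        # 0.02*(0+0.2)/2 = 0.002; the vertical jump to sens 0.6 at fpr 0.02
        # gives 0; segment (0.02,0.6)->(1,1) clipped at fpr 0.05 has
        # sens(0.05) = 0.6 + 0.03/0.98*0.4, giving 0.03*(0.6+s)/2
        sens = np.array([0.0, 0.2, 0.6, 1.0])
        spec = np.array([1.0, 0.98, 0.98, 0.0])
        raw, _ = partial_auc(sens, spec)
        s_edge = 0.6 + 0.03 / 0.98 * 0.4
        expected = 0.002 + 0.03 * (0.6 + s_edge) / 2
        assert raw == pytest.approx(expected, abs=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            partial_auc(np.array([0.0, 1.0]), np.array([1.0, 0.0]), 0.99, 0.95)


class TestSensitivityAtSpecificity:
    def test_printed_confusion_matrix_reconstruction(self):
        # 129 controls with 6 above the cutoff, 15 cases with 8 above:
        # specificity 123/129 = 95.3%, sensitivity 8/15 -> 53%
        controls = np.r_[np.linspace(0.0, 0.40, 123), np.linspace(0.6, 1.0, 6)]
        cases = np.r_[np.linspace(0.05, 0.38, 7), np.linspace(0.62, 0.99, 8)]
        scores = np.r_[controls, cases]
        labels = np.r_[np.zeros(129), np.ones(15)].astype(bool)
        rep = sensitivity_at_specificity(scores, labels, 0.95)
        assert rep.confusion == {"tn": 123, "fp": 6, "fn": 7, "tp": 8}
        assert round_pct(100 * rep.sens_at_spec) == 53
        realized_spec = rep.confusion["tn"] / 129
        assert realized_spec >= 0.95
        assert [round_pct(100 * c) for c in rep.ci] == [27, 79]

    def test_perfect_separation(self):
        scores = np.r_[np.zeros(20), np.ones(5)]
        labels = scores > 0
        rep = sensitivity_at_specificity(scores, labels)
        assert rep.sens_at_spec == 1.0
        assert rep.confusion["fp"] == 0

    def test_all_tied_scores_sensitivity_zero(self):
        labels = np.r_[np.zeros(20), np.ones(5)].astype(bool)
        rep = sensitivity_at_specificity(np.ones(25), labels)
        assert rep.sens_at_spec == 0.0
        assert rep.threshold == np.inf

    @pytest.mark.parametrize("seed", range(10))
    def test_realized_specificity_never_below_target(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 7), size=60)
        labels = rng.random(60) < 0.3
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        rep = sensitivity_at_specificity(scores, labels, 0.95)
        n_neg = int((~labels).sum())
        assert rep.confusion["tn"] / n_neg >= 0.95


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (8, 15, (27, 79)),
            (2, 15, (2, 40)),
            (5, 56, (3, 20)),
        ],
    )
    def test_reported_intervals(self, x, n, expected):
        lo, hi = clopper_pearson(x, n)
        assert (round_pct(100 * lo), round_pct(100 * hi)) == expected

    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_coverage_against_scipy_binomtest(self):
        ref = stats.binomtest(8, 15).proportion_ci(0.95, method="exact")
        lo, hi = clopper_pearson(8, 15)
        assert lo == pytest.approx(ref.low, abs=1e-12)
        assert hi == pytest.approx(ref.high, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestBootstrapCompare:
    def _scores(self, seed=0, n_case=30, n_ctrl=30):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(n_case), np.zeros(n_ctrl)].astype(bool)
        good = np.r_[rng.normal(3, 1, n_case), rng.normal(0, 1, n_ctrl)]
        noise = rng.normal(0, 1, n_case + n_ctrl)
        return good, noise, labels

    def test_identical_vectors_give_p_one(self):
        good, _, labels = self._scores()
        res = compare_pauc_bootstrap(good, good.copy(), labels, n_boot=50, seed=1)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_seeded_determinism(self):
        good, noise, labels = self._scores()
        a = compare_pauc_bootstrap(good, noise, labels, n_boot=100, seed=7)
        b = compare_pauc_bootstrap(good, noise, labels, n_boot=100, seed=7)
        assert (a.delta, a.d_stat, a.p_value) == (b.delta, b.d_stat, b.p_value)

    def test_power_against_pure_noise(self):
        hits = 0
        for seed in range(10):
            good, noise, labels = self._scores(seed, 60, 60)
            res = compare_pauc_bootstrap(good, noise, labels, n_boot=300, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 9

    def test_null_rejection_rate_is_controlled(self):
        rng = np.random.default_rng(42)
        labels = np.r_[np.ones(40), np.zeros(40)].astype(bool)
        rejections = 0
        n_rep = 100
        for i in range(n_rep):
            a = rng.normal(size=80)
            b = rng.normal(size=80)
            res = compare_pauc_bootstrap(a, b, labels, n_boot=200, seed=i)
            rejections += res.p_value < 0.05
        assert 0.0 <= rejections / n_rep <= 0.09


class TestHeldOut:
    def test_counts_and_ci(self):
        scores = np.r_[np.full(51, 0.1), np.full(5, 0.9)]
        res = apply_to_held_out(0.5, scores)
        assert res.n_positive == 5 and res.n_total == 56
        assert round_pct(100 * res.fraction) == 9
        assert [round_pct(100 * c) for c in res.ci] == [3, 20]

    def test_all_below_threshold(self):
        res = apply_to_held_out(0.5, np.zeros(10))
        assert res.n_positive == 0 and res.ci[0] == 0.0

    def test_minus_infinite_threshold_takes_all(self):
        res = apply_to_held_out(-np.inf, np.zeros(10))
        assert res.n_positive == 10

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            apply_to_held_out(0.5, np.array([]))


@pytest.fixture(scope="module")
def cohort():
    design = CohortDesign(
        n_controls=30, n_low_risk=0, n_high_risk=15, n_crc=0,
        n_proteins=40, n_differential_hr=3, n_differential_crc=3,
        effect_log2fc=[2.0, 2.0, 2.0], seed=21,
    )
    m, table, truth = generate_cohort(design)
    y = (table.diagnosis == "high_risk_adenoma").astype(int)
    return m, y, truth


class TestLoocv:
    def test_one_probability_per_sample_in_unit_interval(self, cohort):
        m, y, truth = cohort
        cands = m.protein_ids[:8]
        cv = loocv_predict(m, y, cands, 2, lasso.PathSpec(n_lambda=40))
        assert len(cv.prob) == m.n_samples
        assert ((cv.prob > 0) & (cv.prob < 1)).all()
        assert all(0 <= f <= 1 for f in cv.selection_frequency.values())

    def test_no_leakage_fold_matches_manual_refit(self, cohort):
        m, y, truth = cohort
        cands = m.protein_ids[3:9]
        spec = lasso.PathSpec(n_lambda=30)
        cv = loocv_predict(m, y, cands, 2, spec)
        i = 5  # recompute fold 5 from scratch without sample 5
        train = [j for j in range(m.n_samples) if j != i]
        m_train = m.subset_samples(train)
        X, tf = lasso.build_features(m_train, cands)
        panel = lasso.select_panel(X, y[train], 2, spec, tf.feature_names)
        assert panel.status == "constructed"
        x_test = tf.apply(m.subset_samples([i]))
        assert lasso.predict_prob(panel.model, x_test)[0] == pytest.approx(
            cv.prob[i], abs=1e-12
        )

    def test_signal_free_features_give_chance_level_pauc(self):
        design = CohortDesign(
            n_controls=40, n_low_risk=0, n_high_risk=20, n_crc=0,
            n_proteins=40, n_differential_hr=0, n_differential_crc=0,
            bleeding_log_mean={c: 0.0 for c in
                               ("control", "low_risk_adenoma",
                                "high_risk_adenoma", "crc")},
            seed=22,
        )
        m, table, _ = generate_cohort(design)
        y = (table.diagnosis == "high_risk_adenoma").astype(int)
        cv = loocv_predict(m, y, m.protein_ids[3:13], 2, lasso.PathSpec(n_lambda=30))
        rep = sensitivity_at_specificity(cv.prob, y.astype(bool))
        assert 0.4 <= rep.pauc_std <= 0.65

    def test_too_few_cases_rejected(self, cohort):
        m, y, _ = cohort
        with pytest.raises(ValueError):
            loocv_predict(m, np.r_[1, np.zeros(m.n_samples - 1)], m.protein_ids[:4], 2)
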