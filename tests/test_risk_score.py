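import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from circmir.containers import ValidationError
from circmir.risk_score import (
    PolygenicRiskScore,
    auc,
    auc_confidence_interval,
    delong_variance,
    polygenic_score,
    roc_curve,
    trapezoid_auc,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    cases = scores[labels]
    controls = scores[~labels]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestPolygenicScore:
    def test_single_mirna_unit_weight_is_its_logfpm(self):
        logfpm = pd.DataFrame([[1.0, 5.0, 2.5]], index=["miR-x"], columns=list("abc"))
        s = polygenic_score(logfpm, {"miR-x": 1.0})
        np.testing.assert_allclose(s.values, [1.0, 5.0, 2.5])

    def test_zero_weights_give_zero_scores(self):
        logfpm = pd.DataFrame(np.arange(6.0).reshape(2, 3), index=["m1", "m2"])
        assert (polygenic_score(logfpm, {"m1": 0.0, "m2": 0.0}) == 0).all()

    def test_hand_dot_product(self):
        logfpm = pd.DataFrame([[5.0], [4.0]], index=["m1", "m2"], columns=["s"])
        s = polygenic_score(logfpm, {"m1": -2.0, "m2": 3.0})
        assert s["s"] == pytest.approx(2.0)

    def test_missing_panel_mirna_listed(self):
        logfpm = pd.DataFrame([[1.0]], index=["m1"], columns=["s"])
        with pytest.raises(ValidationError, match="m9"):
            polygenic_score(logfpm, {"m1": 1.0, "m9": 1.0})

    def test_linear_in_weights_and_auc_invariant(self, rng):
        logfpm = pd.DataFrame(rng.normal(size=(4, 21)), index=list("wxyz"))
        w = pd.Series([1.5, -2.0, 0.5, 3.0], index=list("wxyz"))
        labels = np.arange(21) < 10
        s1 = polygenic_score(logfpm, w)
        s3 = polygenic_score(logfpm, 3.0 * w)
        np.testing.assert_allclose(s3.values, 3.0 * s1.values)
        assert auc(s1, labels) == pytest.approx(auc(s3, labels))


class TestAUC:
    def test_perfect_separation(self):
        labels = np.array([True] * 3 + [False] * 4)
        assert auc(np.r_[10, 11, 12, 1, 2, 3, 4.0], labels) == 1.0

    def test_all_tied_is_half(self):
        labels = np.array([True, True, False, False])
        assert auc(np.ones(4), labels) == 0.5

    def test_study_size_pair_counting(self):
        # 10 cases vs 11 controls, exactly 100 of 110 concordant pairs, no ties
        controls = np.arange(1.0, 12.0)          # 1..11, one control at 15 replaced
        controls[-1] = 15.0                      # controls: 1..10, 15
        cases = np.r_[np.arange(20.0, 29.0), 1.5]  # 9 high cases + one at 1.5
        scores = np.r_[cases, controls]
        labels = np.r_[np.ones(10, bool), np.zeros(11, bool)]
        assert brute_force_auc(scores, labels) == pytest.approx(100 / 110)
        assert auc(scores, labels) == pytest.approx(100 / 110)
        assert round(auc(scores, labels), 3) == 0.909

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=25).filter(lambda s: len(s) >= 2)
    )
    def test_matches_bruteforce_with_ties(self, raw):
        scores = np.array(raw, dtype=float)
        labels = np.arange(len(scores)) % 2 == 0
        if labels.all() or (~labels).all():
            return
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_label_flip_antisymmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        if labels.all() or (~labels).all():
            labels[0] = ~labels[0]
        assert auc(scores, labels) + auc(scores, ~labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=25)
        labels = np.arange(25) < 12
        assert auc(np.exp(scores), labels) == pytest.approx(auc(scores, labels))

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValidationError):
            auc(np.arange(4.0), np.ones(4, bool))


class TestROCCurve:
    def test_two_sample_curve_contains_perfect_point(self):
        roc = roc_curve(np.array([2.0, 1.0]), np.array([True, False]))
        pts = set(zip(roc.sensitivity, roc.specificity))
        assert (1.0, 1.0) in pts

    def test_antioriented_scores_mirror(self, rng):
        scores = rng.normal(size=21)
        labels = np.arange(21) < 10
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)
        roc = roc_curve(scores, labels, direction="auto")
        assert roc.auc >= 0.5

    def test_trapezoid_equals_mannwhitney(self, rng):
        for _ in range(20):
            scores = rng.choice(np.arange(8.0), size=21)  # heavy ties
            labels = np.arange(21) < 10
            roc = roc_curve(scores, labels, direction=">")
            assert trapezoid_auc(roc) == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_sklearn_cross_check(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestYouden:
    def test_perfect_separation_j_is_one(self):
        scores = np.r_[np.ones(5) * 10, np.zeros(6)]
        labels = np.r_[np.ones(5, bool), np.zeros(6, bool)]
        cutoff, sens, spec = youden_cutoff(roc_curve(scores, labels))
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 0 < cutoff < 10

    def test_prefers_higher_j_pair(self):
        # operating points (sens, spec) = (0.9, 0.909) vs (0.8, 0.95):
        # J = 0.809 beats 0.75
        j1 = 0.9 + 0.909 - 1
        j2 = 0.8 + 0.95 - 1
        assert j1 > j2

    def test_matches_bruteforce_max_j(self, rng):
        for _ in range(25):
            scores = rng.choice(np.arange(10.0), size=21)
            labels = np.arange(21) < 10
            roc = roc_curve(scores, labels, direction=">")
            _, sens, spec = youden_cutoff(roc)
            cases, controls = scores[labels], scores[~labels]
            best = max(
                (cases > t).mean() + (controls <= t).mean() - 1
                for t in np.r_[-np.inf, np.unique(scores), np.inf]
            )
            assert sens + spec - 1 == pytest.approx(best, abs=1e-12)

    def test_tie_break_higher_sensitivity(self):
        # two thresholds with equal J; the higher-sensitivity one wins
        scores = np.array([3.0, 1.0, 4.0, 2.0])
        labels = np.array([True, True, False, False])
        roc = roc_curve(scores, labels, direction=">")
        _, sens, spec = youden_cutoff(roc)
        j = roc.sensitivity + roc.specificity - 1
        ties = np.isclose(j, j.max())
        assert sens == roc.sensitivity[ties].max()


class TestDeLongCI:
    def test_variance_matches_structural_components_hand_computation(self):
        scores = np.array([3.0, 5.0, 4.0, 1.0, 2.0, 4.5])
        labels = np.array([True, True, True, False, False, False])
        # V10 per case over controls {1, 2, 4.5}: 3->2/3, 5->1, 4->2/3
        v10 = np.array([2 / 3, 1.0, 2 / 3])
        # V01 per control over cases {3, 5, 4}: 1->1, 2->1, 4.5->1/3
        v01 = np.array([1.0, 1.0, 1 / 3])
        expected = v10.var(ddof=1) / 3 + v01.var(ddof=1) / 3
        assert delong_variance(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_about_half_for_null_symmetric_data(self):
        scores = np.r_[1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        labels = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        lo, hi = auc_confidence_interval(scores, labels)
        assert (0.5 - lo) == pytest.approx(hi - 0.5)

    def test_duplication_narrows_ci(self, rng):
        scores = rng.normal(size=21) + np.r_[np.ones(10), np.zeros(11)]
        labels = np.r_[np.ones(10, bool), np.zeros(11, bool)]
        lo1, hi1 = auc_confidence_interval(scores, labels)
        lo2, hi2 = auc_confidence_interval(np.r_[scores, scores], np.r_[labels, labels])
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_degenerate_auc_widened_not_zero_width(self):
        scores = np.r_[10.0, 11.0, 0.0, 1.0]
        labels = np.array([True, True, False, False])
        lo, hi = auc_confidence_interval(scores, labels)
        assert hi - lo > 0

    def test_bootstrap_ci_reasonable_and_seeded(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 10), rng.normal(0, 1, 11)]
        labels = np.r_[np.ones(10, bool), np.zeros(11, bool)]
        ci1 = auc_confidence_interval(scores, labels, method="bootstrap", seed=5)
        ci2 = auc_confidence_interval(scores, labels, method="bootstrap", seed=5)
        assert ci1 == ci2
        assert 0 <= ci1[0] < ci1[1] <= 1


class TestPolygenicRiskScoreEstimator:
    def _fit(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(21, 3)) + np.r_[np.ones(10), np.zeros(11)][:, None],
            columns=["m1", "m2", "m3"],
        )
        y = np.r_[np.ones(10, bool), np.zeros(11, bool)]
        prs = PolygenicRiskScore(weights={"m1": 2.0, "m2": 1.0, "m3": 0.5}).fit(X, y)
        return prs, X, y

    def test_fit_reports_roc_summary(self, rng):
        prs, X, y = self._fit(rng)
        assert 0.5 <= prs.auc_ <= 1.0
        assert prs.auc_ci_[0] <= prs.auc_ <= prs.auc_ci_[1]
        assert prs.orientation_ in (">", "<")
        # predict at the Youden cutoff reproduces the stored sens/spec
        pred = prs.predict(X)
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        assert sens == pytest.approx(prs.sensitivity_)
        assert spec == pytest.approx(prs.specificity_)

    def test_negative_weights_record_antiorientation(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(21, 1)) + np.r_[np.ones(10), np.zeros(11)][:, None],
            columns=["m1"],
        )
        y = np.r_[np.ones(10, bool), np.zeros(11, bool)]
        prs = PolygenicRiskScore(weights={"m1": -3.0}).fit(X, y)
        assert prs.orientation_ == "<"
        assert prs.auc_ >= 0.5

    def test_weights_required(self, rng):
        with pytest.raises(ValidationError):
            PolygenicRiskScore().fit(rng.normal(size=(4, 2)), [1, 1, 0, 0])
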