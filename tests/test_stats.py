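"""Diagnostic and agreement statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from ssokit import (Confusion2x2, UndefinedMetricError, cohens_kappa, cv_auc,
                    diagnostic_summary, icc_category, icc_two_way, roc_points,
                    youden_optimal_cutoff)


# ---------------------------------------------------------------------------
# 2x2 summaries


class TestDiagnosticSummary:
    def test_sso_column_from_published_counts(self):
        # among 86 negative studies: switch-off in 54/67 TN and 7/19 FN
        rep = diagnostic_summary(Confusion2x2(54, 7, 13, 12),
                                 "marker_conditional").report()
        assert rep["sensitivity_pct"] == 88.5
        assert rep["specificity_pct"] == 48.0
        assert rep["accuracy_pct"] == 76.7
        assert rep["lr_pos"] == 1.70
        assert rep["lr_neg"] == 0.24

    def test_spleen_myo_column_from_published_counts(self):
        rep = diagnostic_summary(Confusion2x2(52, 5, 15, 14),
                                 "marker_conditional").report()
        assert rep["sensitivity_pct"] == 91.2
        assert rep["specificity_pct"] == 48.3
        assert rep["lr_pos"] == 1.76
        assert rep["lr_neg"] == 0.18

    def test_conventions_are_transpose_duals(self):
        t = Confusion2x2(54, 7, 13, 12)
        a = diagnostic_summary(t, "marker_conditional")
        b = diagnostic_summary(t.transposed(), "outcome_conditional")
        assert a.sensitivity == pytest.approx(b.sensitivity)
        assert a.specificity == pytest.approx(b.specificity)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40),
           st.integers(1, 40))
    @settings(max_examples=100, derandomize=True)
    def test_lr_identities(self, a, b, c, d):
        for conv in ("marker_conditional", "outcome_conditional"):
            try:
                s = diagnostic_summary(Confusion2x2(a, b, c, d), conv)
            except UndefinedMetricError:
                continue
            assert abs(s.lr_pos * (1 - s.specificity) - s.sensitivity) < 1e-12
            assert abs(s.lr_neg * s.specificity - (1 - s.sensitivity)) < 1e-12
            assert 0 <= s.sensitivity <= 1 and 0 <= s.specificity <= 1

    def test_zero_margin_raises(self):
        with pytest.raises(UndefinedMetricError, match="margin"):
            diagnostic_summary(Confusion2x2(0, 0, 3, 4), "marker_conditional")

    def test_perfect_specificity_lr_undefined(self):
        with pytest.raises(UndefinedMetricError, match="LR\\+"):
            diagnostic_summary(Confusion2x2(5, 0, 0, 5), "marker_conditional")


# ---------------------------------------------------------------------------
# ROC / Youden / cvAUC


def brute_force_concordance(scores, labels, direction="lower_is_positive"):
    """Tie-corrected pairwise concordance over all positive x negative pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            better = p < q if direction == "lower_is_positive" else p > q
            total += 1.0 if better else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _j_and_npos(scores, labels, cut, direction):
    called = scores <= cut if direction == "lower_is_positive" else scores >= cut
    tpr = (called & labels).sum() / labels.sum()
    fpr = (called & ~labels).sum() / (~labels).sum()
    return tpr - fpr, int(called.sum())


def brute_force_youden(scores, labels, direction="lower_is_positive"):
    """Exhaustive search: best J, fewest positive calls among maximizers."""
    best_j, best_npos = -np.inf, None
    cuts = np.concatenate([[-np.inf if direction == "lower_is_positive" else np.inf],
                           np.unique(scores)])
    for c in cuts:
        j, npos = _j_and_npos(scores, labels, c, direction)
        if j > best_j or (j == best_j and npos < best_npos):
            best_j, best_npos = j, npos
    return best_j, best_npos


@st.composite
def scored_sample(draw):
    n = draw(st.integers(4, 50))
    scores = np.array(draw(st.lists(
        st.integers(0, 10), min_size=n, max_size=n)), dtype=float)
    labels = np.array(draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    if labels.all() or not labels.any():
        labels[0] = True
        labels[-1] = False
    return scores, labels


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        labels = np.array([True, True, True, False, False])
        roc = roc_points(scores, labels, "lower_is_positive")
        assert roc.auc == 1.0
        # Youden cutoff lies between the classes and calls exactly the positives
        assert 0.3 < roc.youden_cutoff < 0.8
        assert np.array_equal(scores <= roc.youden_cutoff, labels)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert abs(roc_points(scores, labels).auc - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_points(np.arange(5.0), np.ones(5, dtype=bool))

    @given(scored_sample())
    @settings(max_examples=150, derandomize=True)
    def test_auc_equals_pairwise_concordance(self, sample):
        scores, labels = sample
        for direction in ("lower_is_positive", "higher_is_positive"):
            roc = roc_points(scores, labels, direction)
            assert roc.auc == pytest.approx(
                brute_force_concordance(scores, labels, direction), abs=1e-12)
            assert np.all(np.diff(roc.tpr) >= 0)
            assert np.all(np.diff(roc.fpr) >= 0)

    @given(scored_sample())
    @settings(max_examples=100, derandomize=True)
    def test_auc_matches_sklearn(self, sample):
        scores, labels = sample
        assert roc_points(scores, labels, "higher_is_positive").auc == \
            pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(scored_sample())
    @settings(max_examples=100, derandomize=True)
    def test_youden_matches_exhaustive_search(self, sample):
        # the returned cutoff achieves the exhaustively-searched maximum J
        # with the fewest positive calls among all maximizing cutoffs
        scores, labels = sample
        for direction in ("lower_is_positive", "higher_is_positive"):
            roc = roc_points(scores, labels, direction)
            cut = youden_optimal_cutoff(roc)
            assert cut == roc.youden_cutoff
            best_j, best_npos = brute_force_youden(scores, labels, direction)
            j, npos = _j_and_npos(scores, labels, cut, direction)
            assert j == pytest.approx(best_j, abs=1e-12)
            assert npos == best_npos


class TestCrossValAUC:
    def test_perfect_separation_every_fold(self):
        scores = np.concatenate([np.linspace(0, 0.3, 30), np.linspace(0.5, 1.1, 30)])
        labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        res = cv_auc(scores, labels, k=5, seed=0)
        assert np.all(res.fold_aucs == 1.0)
        assert res.cv_auc == 1.0

    def test_binormal_closed_form(self):
        # scores ~ N(delta, 1) vs N(0, 1): AUC = Phi(delta / sqrt(2))
        rng = np.random.default_rng(12)
        delta = 1.0
        n = 2000
        scores = np.concatenate([rng.normal(delta, 1, n), rng.normal(0, 1, n)])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        res = cv_auc(scores, labels, k=5, seed=1, direction="higher_is_positive")
        assert res.cv_auc == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.02)
        assert res.ci_low <= res.cv_auc <= res.ci_high
        # CI width at n = 4000 should be narrow but nonzero
        assert 0 < res.ci_high - res.ci_low < 0.1

    def test_cv_mean_converges_to_full_sample_auc(self):
        rng = np.random.default_rng(7)
        n = 2000
        scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        full = roc_points(scores, labels, "higher_is_positive").auc
        res = cv_auc(scores, labels, k=5, seed=2, direction="higher_is_positive")
        assert abs(res.cv_auc - full) < 0.01

    def test_determinism(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        a = cv_auc(scores, labels, k=5, seed=9)
        b = cv_auc(scores, labels, k=5, seed=9)
        assert a.cv_auc == b.cv_auc
        assert np.array_equal(a.fold_aucs, b.fold_aucs)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_class_too_small_for_stratification(self):
        scores = np.arange(10.0)
        labels = np.zeros(10, bool)
        labels[:3] = True
        with pytest.raises(UndefinedMetricError, match="stratify"):
            cv_auc(scores, labels, k=5, seed=0)


# ---------------------------------------------------------------------------
# agreement


class TestKappa:
    def test_perfect_agreement(self):
        a = np.array([True, False, True, False])
        assert cohens_kappa(a, a) == 1.0

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.random(20000) < 0.5
        b = rng.random(20000) < 0.5
        assert abs(cohens_kappa(a, b)) < 0.02

    def test_hand_computed_table(self):
        # table: both yes 20, a-only 5, b-only 10, both no 15 (n=50)
        a = np.array([True] * 25 + [False] * 25)
        b = np.array([True] * 20 + [False] * 5 + [True] * 10 + [False] * 15)
        p_o = (20 + 15) / 50
        p_e = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
        assert cohens_kappa(a, b) == pytest.approx((p_o - p_e) / (1 - p_e))

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_matches_sklearn_and_bounded(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        try:
            k = cohens_kappa(a, b)
        except UndefinedMetricError:
            return
        assert k <= 1.0 + 1e-12
        assert k == pytest.approx(
            cohen_kappa_score(a.astype(int), b.astype(int)), abs=1e-12)
        if k == 1.0:
            assert np.array_equal(a, b)

    def test_constant_raters_undefined(self):
        ones = np.ones(10, bool)
        with pytest.raises(UndefinedMetricError):
            cohens_kappa(ones, ones)


class TestICC:
    def test_identical_raters_excellent(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_two_way(x)
        assert res.icc == pytest.approx(1.0)
        assert res.icc_category == "excellent"

    def test_recovers_variance_components(self):
        # x_ij = s_i + r_j + e_ij: ICC(2,1) = 4 / (4 + 0.25 + 1) = 0.762
        rng = np.random.default_rng(0)
        n, k = 1000, 2
        s = rng.normal(0, 2.0, size=(n, 1))
        r = rng.normal(0, 0.5, size=(1, k))
        e = rng.normal(0, 1.0, size=(n, k))
        res = icc_two_way(s + r + e)
        assert res.icc == pytest.approx(4 / 5.25, abs=0.05)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 3)) + rng.normal(0, 2, size=(30, 1))
        df = pd.DataFrame(x).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        icc_pg = pg.intraclass_corr(df, targets="index", raters="rater",
                                    ratings="score")
        expected = icc_pg.loc[icc_pg["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_two_way(x).icc == pytest.approx(float(expected), abs=1e-9)

    def test_zero_between_subject_variance(self):
        with pytest.raises(UndefinedMetricError):
            icc_two_way(np.ones((5, 2)))

    @pytest.mark.parametrize("icc, cat", [
        (0.49, "poor"), (0.5, "moderate"), (0.74, "moderate"),
        (0.75, "good"), (0.82, "good"), (0.89, "good"), (0.9, "excellent"),
    ])
    def test_categories(self, icc, cat):
        assert icc_category(icc) == cat
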