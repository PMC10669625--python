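"""Logistic scoring, ROC/Youden, confusion metrics, repeated-split evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import breathkin as bk
from breathkin.classify import ConfusionMatrix, confusion_at_threshold
from breathkin.errors import InvalidInputError


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _loglik(x, y, b0, b1, ridge=0.0):
    eta = b0 + b1 * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))) - 0.5 * ridge * b1 ** 2)


class TestFitLogistic:
    def test_uninformative_feature_closed_form(self):
        # same x distribution in both classes -> coef 0, intercept ln(n1/n0)
        x = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1, 1, 1])
        fit = bk.fit_logistic(x, y)
        assert fit.coefficient == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(math.log(4 / 2), abs=1e-8)
        assert not fit.separated

    def test_matches_likelihood_grid_oracle(self):
        x = np.array([-1.2, -0.5, 0.3, 0.8, 1.5, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        fit = bk.fit_logistic(x, y)
        # brute-force 2-D grid: coarse pass then 1e-3 refinement
        b0s = np.arange(-5, 5, 0.1)
        b1s = np.arange(-5, 5, 0.1)
        ll = np.array([[_loglik(x, y, a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0s = np.arange(b0s[i] - 0.15, b0s[i] + 0.15, 1e-3)
        b1s = np.arange(b1s[j] - 0.15, b1s[j] + 0.15, 1e-3)
        ll = np.array([[_loglik(x, y, a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.intercept == pytest.approx(b0s[i], abs=1e-2)
        assert fit.coefficient == pytest.approx(b1s[j], abs=1e-2)

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        fit = bk.fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.coefficient == pytest.approx(ref.params[1], abs=1e-6)

    def test_separation_flagged_and_penalized(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = bk.fit_logistic(x, y)
        assert fit.separated
        assert np.isfinite(fit.coefficient)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            bk.fit_logistic(np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# ROC / AUROC / Youden
# ---------------------------------------------------------------------------

class TestRoc:
    def test_separated_scores_give_one(self):
        assert bk.roc_auroc([1, 2, 3, 11, 12, 13], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_identical_scores_give_half(self):
        assert bk.roc_auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_tied_pair_half_credit(self):
        # 4 positive-negative pairs: wins 3.5/4
        assert bk.roc_auroc([1, 2, 2, 3], [0, 1, 0, 1]) == pytest.approx(0.875)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.integers(0, 10, size=30).astype(float)  # force ties
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            assert bk.roc_auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=30))
    def test_score_negation_complements(self, scores):
        n = len(scores)
        y = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        s = np.asarray(scores)
        assert bk.roc_auroc(s, y) + bk.roc_auroc(-s, y) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(40)
        y = rng.integers(0, 2, size=40)
        a1 = bk.roc_auroc(s, y)
        assert bk.roc_auroc(np.exp(s), y) == pytest.approx(a1, abs=1e-12)
        assert bk.roc_auroc(3 * s + 7, y) == pytest.approx(a1, abs=1e-12)


class TestYouden:
    def test_separated_groups_report_gap_midpoint(self):
        roc = bk.roc_curve([1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1])
        thr, sens, spec = bk.youden_threshold(roc)
        assert sens == spec == 1.0
        assert thr == pytest.approx(5.0)

    def test_constant_scores_give_zero_j(self):
        roc = bk.roc_curve([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1])
        thr, sens, spec = bk.youden_threshold(roc)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_agrees_with_exhaustive_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            s = np.round(rng.standard_normal(8), 2)
            y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
            roc = bk.roc_curve(s, y)
            thr, sens, spec = bk.youden_threshold(roc)
            # oracle: brute force over a dense threshold sweep
            cands = np.concatenate([s - 1e-6, s + 1e-6, [s.min() - 1, s.max() + 1]])
            best = -1.0
            for c in cands:
                pred = s >= c
                se = np.mean(pred[y == 1])
                sp = np.mean(~pred[y == 0])
                best = max(best, se + sp - 1)
            assert sens + spec - 1 == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

class TestConfusionMetrics:
    def test_degenerate_denominators_signalled(self):
        m = bk.confusion_metrics(ConfusionMatrix(tp=29, fp=0, fn=0, tn=29))
        assert m["sens"] == m["spec"] == 1.0
        assert m["ppv_pct"] == m["npv_pct"] == 100.0
        assert math.isinf(m["lr_pos"]) and m["lr_neg"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            ConfusionMatrix(tp=0, fp=0, fn=0, tn=0)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_ppv_equals_bayes_identity(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0 or tp + fn == 0 or tn + fp == 0 or tp + fp == 0:
            return
        m = bk.confusion_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        total = tp + fp + fn + tn
        pi = (tp + fn) / total
        bayes = m["sens"] * pi / (m["sens"] * pi + (1 - m["spec"]) * (1 - pi))
        assert m["ppv_pct"] / 100 == pytest.approx(bayes, abs=1e-12)


# ---------------------------------------------------------------------------
# repeated-split evaluation
# ---------------------------------------------------------------------------

class TestEvaluateTimepoints:
    def test_fixed_seed_reproducible(self, default_cohort, default_kinetics):
        _, washout = default_cohort
        r1 = bk.evaluate_timepoints(washout, default_kinetics, seed=5)
        r2 = bk.evaluate_timepoints(washout, default_kinetics, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_separated_groups_score_perfectly(self):
        rows = []
        for i in range(8):
            for t in (0, 20, 40):
                rows.append((f"c{i}", "control", t, 10.0 + i + t, False))
                rows.append((f"d{i}", "cirrhosis", t, 1000.0 + i + t, False))
        washout = pd.DataFrame(rows, columns=[
            "subject_id", "group", "timepoint_min", "limonene_ng", "censored"])
        kin = pd.DataFrame({
            "subject_id": [f"c{i}" for i in range(8)] + [f"d{i}" for i in range(8)],
            "group": ["control"] * 8 + ["cirrhosis"] * 8,
            "cmax_ng": list(50.0 + np.arange(8)) + list(5000.0 + np.arange(8)),
        })
        rep = bk.evaluate_timepoints(washout, kin, seed=3)
        assert (rep["auroc_mean"] == 1.0).all()
        assert (rep["sens_mean"] == 1.0).all()
        assert (rep["spec_mean"] == 1.0).all()

    def test_shuffled_labels_are_uninformative(self, default_cohort,
                                               default_kinetics):
        _, washout = default_cohort
        rng = np.random.default_rng(8)
        aurocs = []
        for _ in range(20):
            kin = default_kinetics.copy()
            relabel = dict(zip(kin["subject_id"],
                               rng.permutation(kin["group"].to_numpy())))
            kin["group"] = kin["subject_id"].map(relabel)
            w = washout.copy()
            w["group"] = w["subject_id"].map(relabel)
            rep = bk.evaluate_timepoints(w, kin, seed=1, include_cmax=False)
            aurocs.append(rep["auroc_mean"].mean())
        assert abs(np.mean(aurocs) - 0.5) < 0.15

    def test_whole_cohort_counts_consistent(self, default_cohort, default_kinetics):
        _, washout = default_cohort
        rep = bk.evaluate_timepoints(washout, default_kinetics, seed=5)
        for row in rep.itertuples():
            cm = ConfusionMatrix(tp=row.tp, fp=row.fp, fn=row.fn, tn=row.tn)
            m = bk.confusion_metrics(cm)
            assert m["sens"] == pytest.approx(row.sens_whole)
            assert m["spec"] == pytest.approx(row.spec_whole)

    def test_small_class_rejected(self):
        washout = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"], "group": ["control"] * 2 + ["cirrhosis"] * 2,
            "timepoint_min": [20] * 4, "limonene_ng": [1.0, 2.0, 3.0, 4.0],
            "censored": [False] * 4})
        kin = pd.DataFrame({"subject_id": ["a", "b", "c", "d"],
                            "group": ["control"] * 2 + ["cirrhosis"] * 2,
                            "cmax_ng": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(InvalidInputError):
            bk.evaluate_timepoints(washout, kin, seed=0)

    def test_kfold_scheme_runs(self, default_cohort, default_kinetics):
        _, washout = default_cohort
        rep = bk.evaluate_timepoints(washout, default_kinetics, scheme="kfold",
                                     seed=2, include_cmax=False)
        assert len(rep) == 6
        assert rep["auroc_mean"].between(0, 1).all()
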