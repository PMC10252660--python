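"""Confusion-matrix metrics, exact binomial intervals, kappa, ROC, and
the survival stack (KM / log-rank / Cox)."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from scarface.evaluation import (
    ConfusionMatrix,
    clopper_pearson,
    cohen_kappa,
    confusion_matrix,
    cox_fit,
    km_logrank,
    metric_report,
    roc_auc,
)


class TestConfusionMatrix:
    def test_all_correct(self):
        cm = confusion_matrix(["p"] * 10 + ["n"] * 10, ["p"] * 10 + ["n"] * 10, "p")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    def test_all_flipped(self):
        cm = confusion_matrix(["n"] * 10 + ["p"] * 10, ["p"] * 10 + ["n"] * 10, "p")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 10, 10)

    def test_matches_bruteforce_tally_on_random_labels(self, rng):
        pred = rng.choice(["p", "n"], size=200)
        act = rng.choice(["p", "n"], size=200)
        cm = confusion_matrix(pred, act, "p")
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for p, a in zip(pred, act):
            key = ("t" if p == a else "f") + ("p" if p == "p" else "n")
            tally[key] += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            confusion_matrix(["x", "p"], ["p", "n"], "p")


class TestMetricReport:
    def test_perfect_matrix_scores_one(self):
        r = metric_report(ConfusionMatrix(5, 5, 0, 0))
        assert (r.accuracy, r.sensitivity, r.specificity, r.kappa) == (1.0, 1.0, 1.0, 1.0)

    def test_empty_rate_denominator_reported_missing(self):
        r = metric_report(ConfusionMatrix(5, 0, 0, 5))
        assert r.sensitivity is None

    def test_kappa_agrees_with_sklearn_on_random_labels(self, rng):
        """Dual route: the closed-form 2x2 kappa equals sklearn's."""
        for _ in range(20):
            pred = rng.choice(["p", "n"], size=100)
            act = rng.choice(["p", "n"], size=100)
            cm = confusion_matrix(pred, act, "p")
            assert cohen_kappa(cm) == pytest.approx(
                cohen_kappa_score(act, pred), abs=1e-12
            )

    def test_kappa_near_zero_for_independent_labels(self, rng):
        pred = rng.choice(["p", "n"], size=10_000)
        act = rng.choice(["p", "n"], size=10_000)
        assert abs(cohen_kappa(confusion_matrix(pred, act, "p"))) < 0.05

    def test_kappa_symmetric_under_class_swap(self, rng):
        cm = ConfusionMatrix(25, 17, 1, 9)
        swapped = ConfusionMatrix(17, 25, 9, 1)
        assert cohen_kappa(cm) == pytest.approx(cohen_kappa(swapped))


class TestClopperPearson:
    def test_boundary_cases(self):
        assert clopper_pearson(52, 52)[1] == 1.0
        assert clopper_pearson(0, 52)[0] == 0.0

    def test_brackets_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            x = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(x, n)
            assert lo <= x / n <= hi

    def test_interval_tightens_with_n(self):
        widths = [
            np.diff(clopper_pearson(int(0.8 * n), n))[0] for n in (10, 50, 250, 1250)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1, 2, 3, 10, 11, 12], ["n"] * 3 + ["p"] * 3, "p")
        assert auc == 1.0

    def test_symmetry_under_score_negation(self, rng):
        scores = rng.normal(size=300)
        act = rng.choice(["p", "n"], size=300)
        _, a1 = roc_auc(scores, act, "p")
        _, a2 = roc_auc(-scores, act, "p")
        assert a1 + a2 == pytest.approx(1.0)

    def test_null_scores_give_half(self, rng):
        scores = rng.normal(size=2000)
        act = rng.choice(["p", "n"], size=2000)
        _, auc = roc_auc(scores, act, "p")
        assert 0.45 < auc < 0.55

    def test_agrees_with_sklearn_including_ties(self, rng):
        scores = rng.integers(0, 5, size=200).astype(float)  # heavy ties
        act = rng.choice(["p", "n"], size=200)
        _, auc = roc_auc(scores, act, "p")
        assert auc == pytest.approx(roc_auc_score(act == "p", scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], ["p", "p"], "p")


class TestKmLogrank:
    def test_five_subject_product_limit_by_hand(self):
        """times 1..5, events 1,1,0,1,0: survival 0.8, 0.6, 0.6, 0.3, 0.3."""
        res = km_logrank([1, 2, 3, 4, 5], [1, 1, 0, 1, 0], ["g"] * 5)
        curve = res.km_curves["g"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.8)
        assert curve.loc[2.0] == pytest.approx(0.6)
        assert curve.loc[3.0] == pytest.approx(0.6)
        assert curve.loc[4.0] == pytest.approx(0.3)
        assert curve.loc[5.0] == pytest.approx(0.3)

    def test_identical_groups_give_zero_chi2(self):
        times = [2, 4, 6, 8, 10, 12]
        events = [1, 1, 0, 1, 1, 0]
        res = km_logrank(times + times, events + events, ["a"] * 6 + ["b"] * 6)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)

    def test_power_against_strong_hazard_ratio(self):
        """Exponential groups with true HR 4 and n=200: log-rank rejects at
        p < 0.01 in at least 95% of replicates."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            t1 = rng.exponential(1.0, size=100)
            t2 = rng.exponential(4.0, size=100)
            res = km_logrank(
                np.r_[t1, t2], np.ones(200, int), ["a"] * 100 + ["b"] * 100
            )
            hits += res.logrank_p < 0.01
        assert hits >= 95

    def test_survival_curves_monotone_non_increasing(self, rng):
        times = rng.exponential(10, size=80)
        events = (rng.random(80) < 0.7).astype(int)
        res = km_logrank(times, events, ["g"] * 80)
        s = res.km_curves["g"]["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert ((0 <= s) & (s <= 1)).all()


class TestCoxFit:
    def test_recovers_true_hazard_ratio(self):
        """Binary covariate with true HR 0.25 on exponential times, n=400."""
        rng = np.random.default_rng(123)
        x = np.r_[np.zeros(200), np.ones(200)]
        scale = np.where(x == 1, 4.0, 1.0)  # HR 0.25 for x=1
        t = rng.exponential(scale)
        res = cox_fit(t, np.ones(400, int), pd.DataFrame({"x": x}))
        hr = float(res.loc["x", "hr"])
        assert 0.17 <= hr <= 0.37

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(5)
        n_rep, covered = 200, 0
        for _ in range(n_rep):
            x = rng.random(120) < 0.5
            t = rng.exponential(1.0, size=120)
            res = cox_fit(t, np.ones(120, int), pd.DataFrame({"x": x.astype(float)}))
            covered += res.loc["x", "ci_low"] <= 1.0 <= res.loc["x", "ci_high"]
        assert 0.90 <= covered / n_rep <= 0.99

    def test_duplicated_covariate_rejected(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="rank"):
            cox_fit(rng.exponential(1, 50), np.ones(50, int), df)

    def test_constant_covariate_rejected(self, rng):
        df = pd.DataFrame({"a": np.ones(30)})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rng.exponential(1, 30), np.ones(30, int), df)
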