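"""Outcome statistics: horizon rules, AUC vs brute-force pair counting,
sensitivity-anchored thresholds vs exhaustive search, Cox vs an explicit
partial-likelihood oracle, Kaplan–Meier/log-rank, and kappa."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from nucmorph import (cohens_kappa, cox_univariate, interpret_kappa,
                      kaplan_meier, lights_kappa, log_rank,
                      precision_from_rates, prepare_cohort, roc_auc,
                      select_threshold)


def _records(rows):
    return pd.DataFrame(rows, columns=["case_id", "time_days", "status", "score"])


class TestPrepareCohort:
    def test_horizon_rules(self):
        df = _records([
            ("a", 400, "alive", 1.0),        # censored at 250
            ("b", 100, "tumor-death", 2.0),  # event at 100, positive
            ("c", 80, "other-death", 3.0),   # censored at 80, not in binary set
            ("d", 50, "lost", 4.0),          # excluded
        ])
        out = prepare_cohort(df, horizon_days=250)
        assert set(out["case_id"]) == {"a", "b", "c"}
        by = out.set_index("case_id")
        assert by.loc["a", "time"] == 250 and by.loc["a", "event"] == 0
        assert by.loc["b", "time"] == 100 and by.loc["b", "event"] == 1
        assert by.loc["c", "time"] == 80 and by.loc["c", "event"] == 0
        assert by.loc["a", "label250"] == 0.0
        assert by.loc["b", "label250"] == 1.0
        assert math.isnan(by.loc["c", "label250"])

    def test_study_style_class_split(self):
        # 46 cases: 8 lost, 3 other-death, 10 tumor-death, 25 alive
        # → binary set of 10 positives and 25 negatives
        rows = (
            [(f"l{i}", 30 + i, "lost", 0.0) for i in range(8)]
            + [(f"o{i}", 60 + i, "other-death", 0.0) for i in range(3)]
            + [(f"t{i}", 100 + i, "tumor-death", 1.0) for i in range(10)]
            + [(f"a{i}", 600 + i, "alive", 0.0) for i in range(25)]
        )
        out = prepare_cohort(_records(rows), horizon_days=250)
        assert len(out) == 38
        assert (out["label250"] == 1.0).sum() == 10
        assert (out["label250"] == 0.0).sum() == 25
        assert out["label250"].isna().sum() == 3

    def test_events_after_horizon_become_censored(self):
        out = prepare_cohort(_records([("x", 300, "tumor-death", 0.0),
                                       ("y", 400, "alive", 0.0)]), 250)
        assert (out["event"] == 0).all()
        assert (out["time"] == 250).all()
        assert (out["label250"] == 0.0).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            prepare_cohort(_records([("x", -1, "alive", 0.0)]))
        with pytest.raises(ValueError):
            prepare_cohort(_records([("x", 10, "vanished", 0.0)]))


class TestRocAuc:
    def test_complete_separation(self):
        r = roc_auc(np.array([2, 3, 0, 1.0]), np.array([1, 1, 0, 0]),
                    ci_method="bootstrap")
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc(np.ones(10), np.array([1] * 4 + [0] * 6),
                    ci_method="bootstrap")
        assert r.auc == 0.5

    def test_one_of_four_pairs(self):
        # positives {1,3}, negatives {2,4}: only (3,2) of 4 pairs wins
        r = roc_auc(np.array([1, 3, 2, 4.0]), np.array([1, 1, 0, 0]),
                    ci_method="bootstrap")
        assert r.auc == 0.25

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_pair_counting(self, data):
        n = data.draw(st.integers(4, 50))
        scores = np.array(data.draw(st.lists(
            st.integers(0, 8), min_size=n, max_size=n)), dtype=float)
        labels = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        r = roc_auc(scores, labels, ci_method="bootstrap", n_boot=10)
        assert r.auc == pytest.approx(expected, abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_delong_ci_contains_point_and_orientation_flag(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 40)])
        labels = np.array([1] * 30 + [0] * 40)
        r = roc_auc(scores, labels)
        assert r.ci_low <= r.auc <= r.ci_high
        assert 0 < r.ci_low and r.ci_high <= 1
        flipped = roc_auc(-scores, labels, higher_is_worse=False)
        assert flipped.auc == pytest.approx(r.auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4))


class TestSelectThreshold:
    def test_worked_example(self):
        # positives {4,5,6}, negatives {1,2,5}: Sen 2/3 is below target, so
        # the anchor lands at Sen 1.0 with the best Sp 2/3 (threshold in (2,4))
        c = select_threshold(np.array([4, 5, 6, 1, 2, 5.0]),
                             np.array([1, 1, 1, 0, 0, 0]), 0.70)
        assert c.sensitivity == 1.0
        assert c.specificity == pytest.approx(2 / 3)
        assert 2 < c.threshold < 4

    def test_separated_classes_reach_full_specificity(self):
        c = select_threshold(np.array([10, 11, 12, 1, 2, 3.0]),
                             np.array([1, 1, 1, 0, 0, 0]), 0.70)
        assert c.sensitivity >= 0.70
        assert c.specificity == 1.0

    def test_ten_positives_anchor_at_exactly_seven(self):
        # 10 distinct positive scores: the minimal admissible Sen classifies
        # exactly 7/10 tumor-death cases correctly
        scores = np.concatenate([np.arange(10, 20), np.arange(5, 30.0)])
        labels = np.array([1] * 10 + [0] * 25)
        c = select_threshold(scores, labels, 0.70)
        assert c.tp == 7
        assert c.sensitivity == pytest.approx(0.70)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_exhaustive_optimality(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(data.draw(st.lists(
            st.integers(0, 9), min_size=n, max_size=n)), dtype=float)
        labels = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        target = data.draw(st.sampled_from([0.5, 0.7, 0.9, 1.0]))
        c = select_threshold(scores, labels, target)
        assert c.sensitivity >= target
        # no candidate with the same sensitivity has higher specificity
        uniq = np.unique(scores)
        cands = np.concatenate([[-np.inf, np.inf], (uniq[:-1] + uniq[1:]) / 2])
        for thr in cands:
            call = scores >= thr
            tp = np.sum(call & (labels == 1)); fn = np.sum(~call & (labels == 1))
            tn = np.sum(~call & (labels == 0)); fp = np.sum(call & (labels == 0))
            sen = tp / (tp + fn); sp = tn / (tn + fp)
            if sen >= target:
                assert (sen, -sp) >= (c.sensitivity, -c.specificity)

    def test_confusion_identities(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        c = select_threshold(scores, labels, 0.7)
        assert c.sensitivity == c.tp / (c.tp + c.fn)
        assert c.specificity == c.tn / (c.tn + c.fp)
        if c.tp + c.fp:
            assert c.precision == c.tp / (c.tp + c.fp)


class TestPrecisionFromRates:
    @pytest.mark.parametrize("sen,sp,npos,nneg,expected", [
        (0.70, 0.68, 10, 25, 7 / 15),   # ≈ 46.7 %
        (0.70, 0.92, 10, 25, 7 / 9),    # ≈ 77.8 %
        (1.00, 1.00, 10, 25, 1.0),
    ])
    def test_reconstruction(self, sen, sp, npos, nneg, expected):
        assert precision_from_rates(sen, sp, npos, nneg) == pytest.approx(expected)

    def test_no_positive_calls_rejected(self):
        with pytest.raises(ValueError):
            precision_from_rates(0.0, 1.0, 10, 25)


class TestCox:
    def test_matches_partial_likelihood_oracle(self):
        # 4 subjects, no ties, mixed groups: 1-D maximization of the
        # explicit partial likelihood is the oracle
        times = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_loglik(beta):
            risk = [list(range(i, 4)) for i in range(4)]
            return -sum(
                beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in rs))
                for i, rs in enumerate(risk)
            )

        oracle = minimize_scalar(neg_loglik, bounds=(-20, 20), method="bounded")
        res = cox_univariate(x, times, np.ones(4, dtype=int))
        assert res.coef == pytest.approx(oracle.x, abs=1e-4)

    def test_complete_separation_reported_non_estimable(self):
        res = cox_univariate(np.array([1.0, 1, 0, 0]),
                             np.array([1.0, 2, 3, 4]), np.ones(4, dtype=int))
        assert not res.estimable
        assert math.isnan(res.hazard_ratio)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cox_univariate(np.array([1.0, 2]), np.array([1.0, 2]),
                           np.array([0, 0]))
        with pytest.raises(ValueError):
            cox_univariate(np.ones(4), np.arange(1.0, 5), np.ones(4, dtype=int))

    def test_null_ci_coverage_calibrated(self):
        # 200 seeded null cohorts at n=100 under the generator defaults:
        # the 95% Wald CI should cover HR = 1 in 90–99% of runs
        from nucmorph import CohortSpec, CovariateSpec, generate_outcome_cohort
        covered = 0
        for s in range(200):
            spec = CohortSpec(n_cases=100,
                              covariates=(CovariateSpec(name="x", log_hr=0.0),),
                              seed=20_000 + s)
            d = generate_outcome_cohort(spec)
            r = cox_univariate(d["x"].to_numpy(), d["time_days"].to_numpy(),
                               d["event"].to_numpy())
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert 180 <= covered <= 198


class TestKaplanMeierLogRank:
    def test_product_limit_all_events(self):
        km = kaplan_meier(np.array([1.0, 2, 3]), np.array([1, 1, 1]),
                          np.zeros(3, dtype=int))
        surv = km.set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = kaplan_meier(np.array([5.0, 6, 7]), np.zeros(3, dtype=int),
                          np.zeros(3, dtype=int))
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.integers(1, 30, size=25).astype(float)
        km = kaplan_meier(t, np.ones(25, dtype=int), np.zeros(25, dtype=int))
        for _, row in km[km.time > 0].iterrows():
            assert row["survival"] == pytest.approx(np.mean(t > row["time"]))

    def test_identical_groups_logrank_null(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.ones(8, dtype=int)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = log_rank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank(np.array([1.0, 2]), np.array([1, 1]), np.array([0, 0]))


class TestKappa:
    def test_identical_raters(self):
        a = np.array([1, 2, 3, 1, 2, 3])
        assert cohens_kappa(a, a) == 1.0

    def test_hand_evaluated_2x2_table(self):
        # agreement table [[20,5],[5,20]]: p_o 0.8, p_e 0.5, kappa 0.6
        a = np.repeat([0, 0, 1, 1], [20, 5, 5, 20])
        b = np.repeat([0, 1, 0, 1], [20, 5, 5, 20])
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_symmetry_and_sklearn_crosscheck(self, rng):
        for _ in range(5):
            a = rng.integers(0, 3, size=60)
            b = rng.integers(0, 3, size=60)
            k = cohens_kappa(a, b)
            assert k == pytest.approx(cohens_kappa(b, a))
            assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_three_identical_raters_lights_kappa_one(self):
        panel = pd.DataFrame({"r1": [1, 2, 3, 2], "r2": [1, 2, 3, 2],
                              "r3": [1, 2, 3, 2]})
        res = lights_kappa(panel)
        assert res.lights_kappa == 1.0
        assert res.interpretation == "almost perfect"
        assert len(res.pairwise) == 3

    def test_degenerate_marginals(self):
        # both raters constant on the same category: agreement is total
        assert cohens_kappa(np.zeros(5), np.zeros(5)) == 1.0
        # constant on different categories: chance agreement 0, kappa 0
        assert cohens_kappa(np.zeros(5), np.ones(5)) == 0.0

    @pytest.mark.parametrize("k,label", [
        (0.204, "slight"),      # rounds to 0.20
        (0.272, "fair"),
        (0.90, "almost perfect"),
        (0.0, "poor"),
        (-0.3, "poor"),
        (0.50, "moderate"),
        (0.75, "substantial"),
    ])
    def test_interpretation_bins(self, k, label):
        assert interpret_kappa(k) == label
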