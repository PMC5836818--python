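import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prognoset.classifier import LinearClassifier
from prognoset.cohorts import KmRecord
from prognoset.evaluation import (
    apply_filtration,
    auc_from_scores,
    dichotomize_by_score,
    km_curve,
    log_rank,
    roc_auc,
)
from prognoset.io import ExpressionMatrix

import pandas as pd


def pair_counting_auc(scores, labels):
    """Exhaustive positive x negative pair enumeration (ties count 1/2)."""
    pos = [scores[k] for k in scores if labels[k]]
    neg = [scores[k] for k in scores if not labels[k]]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 3.0, "b": 2.0, "c": -1.0, "d": -2.0}
        labels = {"a": True, "b": True, "c": False, "d": False}
        assert roc_auc(scores, labels).auc == 1.0

    def test_all_tied_scores(self):
        scores = {k: 0.5 for k in "abcd"}
        labels = {"a": True, "b": True, "c": False, "d": False}
        assert roc_auc(scores, labels).auc == 0.5

    def test_ties_match_pair_counting(self):
        scores = dict(zip("abcdefgh", [1.0, 2.0, 2.0, 3.0, 3.0, 0.0, 4.0, 1.0]))
        labels = dict(zip("abcdefgh", [True, True, False, True, False, False,
                                       True, False]))
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_curve_invariants_and_trapezoid(self):
        rng = np.random.default_rng(3)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=25))}
        labels = {k: i % 3 == 0 for i, k in enumerate(scores)}
        r = roc_auc(scores, labels)
        xs, ys = zip(*r.curve)
        assert r.curve[0] == (0.0, 0.0) and r.curve[-1] == (1.0, 1.0)
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert all(b >= a for a, b in zip(ys, ys[1:]))
        assert np.trapezoid(ys, xs) == pytest.approx(r.auc, abs=1e-9)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc({"a": 1.0}, {"a": True})

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=20),
        st.data(),
    )
    def test_negation_symmetry(self, values, data):
        n = len(values)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda l: any(l) and not all(l)
            )
        )
        s = np.array(values)
        y = np.array(labels)
        assert auc_from_scores(s, y) + auc_from_scores(-s, y) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=30)
        y = rng.random(30) < 0.4
        assert auc_from_scores(np.exp(2 * s) + 7, y) == pytest.approx(
            auc_from_scores(s, y), abs=1e-12
        )


class TestFiltration:
    @pytest.mark.parametrize(
        "train,filters,expect",
        [
            (0.65, {"f1": 0.56, "f2": 0.57}, True),
            (0.60, {"f1": 0.55, "f2": 0.55}, True),  # boundary: not less than
            (0.72, {"f1": 0.54, "f2": 0.70}, False),
            (0.59, {"f1": 0.80, "f2": 0.80}, False),
        ],
    )
    def test_cascade_rule(self, train, filters, expect):
        v = apply_filtration(train, filters)
        assert v.passed is expect

    def test_failing_stage_names_cohort(self):
        v = apply_filtration(0.72, {"f1": 0.54, "f2": 0.70})
        assert v.failing_stage == "filter:f1"
        assert apply_filtration(0.5, {"f1": 0.9}).failing_stage == "train"
        assert apply_filtration(0.7, {"f1": 0.6}).failing_stage is None


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        curve = km_curve([KmRecord(f"s{i}", False, 10.0 + i) for i in range(5)])
        assert curve.times.size == 0  # no drops: survival constantly 1

    def test_single_event_drop(self):
        recs = [KmRecord("e", True, 10.0)] + [
            KmRecord(f"c{i}", False, 20.0) for i in range(4)
        ]
        curve = km_curve(recs)
        np.testing.assert_array_equal(curve.times, [10.0])
        assert curve.survival[0] == pytest.approx(0.8)
        assert curve.at_risk[0] == 5

    def test_mixed_fixture_matches_hand_computed_table(self):
        # events at 5 (n=6 at risk), 8 (n=4), 12 (n=2); censoring at 6 and 8;
        # the censoring tied at 8 stays at risk for that event
        recs = [
            KmRecord("a", True, 5.0),
            KmRecord("b", False, 6.0),
            KmRecord("c", True, 8.0),
            KmRecord("d", False, 8.0),
            KmRecord("e", True, 12.0),
            KmRecord("f", False, 15.0),
        ]
        curve = km_curve(recs)
        np.testing.assert_array_equal(curve.times, [5.0, 8.0, 12.0])
        np.testing.assert_array_equal(curve.at_risk, [6, 4, 2])
        expected = [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2]
        np.testing.assert_allclose(curve.survival, expected, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = np.round(rng.exponential(30, size=40), 1) + 0.1
        recs = [KmRecord(f"s{i}", True, float(t)) for i, t in enumerate(times)]
        curve = km_curve(recs)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([])


def logrank_chi2_oracle(times, events, group, n_perms=None, rng=None):
    """Vectorized log-rank chi-square, optionally over permuted group labels.

    Independent of the package implementation: works directly from the
    observed-minus-expected sums over pooled event times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    uniq = np.unique(times[events])
    at_risk = times[None, :] >= uniq[:, None]  # times x subjects
    died = (times[None, :] == uniq[:, None]) & events[None, :]
    n_tot = at_risk.sum(axis=1)
    d_tot = died.sum(axis=1)
    if n_perms is None:
        groups = np.asarray(group, float)[:, None]
    else:
        groups = np.empty((len(times), n_perms))
        g = np.asarray(group, float)
        for j in range(n_perms):
            groups[:, j] = rng.permutation(g)
    n1 = at_risk @ groups
    d1 = died @ groups
    expected = d_tot[:, None] * n1 / n_tot[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (d_tot[:, None] * (n1 / n_tot[:, None]) * (1 - n1 / n_tot[:, None])
               * (n_tot[:, None] - d_tot[:, None]) / (n_tot[:, None] - 1))
    var = np.nan_to_num(var)
    o_minus_e = (d1 - expected).sum(axis=0)
    v = var.sum(axis=0)
    return o_minus_e ** 2 / v


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = [KmRecord(f"s{i}", i % 2 == 0, 5.0 + i) for i in range(6)]
        g2 = [KmRecord(f"t{i}", r.event, r.time) for i, r in enumerate(g)]
        res = log_rank(g, g2)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(1.0, abs=1e-9)

    def test_group_swap_symmetry(self):
        a = [KmRecord(f"a{i}", True, t) for i, t in enumerate([3.0, 6.0, 9.0])]
        b = [KmRecord(f"b{i}", e, t)
             for i, (e, t) in enumerate([(True, 12.0), (False, 15.0), (True, 20.0)])]
        r1, r2 = log_rank(a, b), log_rank(b, a)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed, abs=1e-12)

    def test_no_events_anywhere(self):
        a = [KmRecord("a", False, 5.0)]
        b = [KmRecord("b", False, 7.0)]
        res = log_rank(a, b)
        assert res.statistic == 0.0
        assert res.p_two_tailed == 1.0

    def test_twelve_subject_fixture_against_permutation_oracle(self):
        times = [2.0, 4.0, 4.0, 7.0, 9.0, 11.0, 3.0, 8.0, 13.0, 16.0, 16.0, 20.0]
        events = [True, True, False, True, True, False,
                  True, False, True, False, True, True]
        group = [1] * 6 + [0] * 6
        a = [KmRecord(f"a{i}", events[i], times[i]) for i in range(6)]
        b = [KmRecord(f"b{i}", events[i + 6], times[i + 6]) for i in range(6)]
        res = log_rank(a, b)
        observed = logrank_chi2_oracle(times, events, group)[0]
        assert res.statistic == pytest.approx(observed, abs=1e-9)
        rng = np.random.default_rng(2024)
        perm_stats = logrank_chi2_oracle(times, events, group, n_perms=50_000,
                                         rng=rng)
        p_perm = (perm_stats >= observed - 1e-12).mean()
        # chi-square p and exact permutation p agree within Monte Carlo and
        # small-sample approximation error
        assert res.p_two_tailed == pytest.approx(p_perm, abs=0.05)


class TestDichotomize:
    x = ExpressionMatrix(
        values=pd.DataFrame({"s0": {"g": 9.0}, "s1": {"g": 8.5},
                             "s2": {"g": 2.0}, "s3": {"g": 2.5}}),
        cohort_of_sample={s: "A" for s in ["s0", "s1", "s2", "s3"]},
    )

    def clf(self, bias=-5.5):
        return LinearClassifier(gene_ids=["g"], weights=[1.0], bias=bias,
                                center=[0.0], scale=[1.0], cost=1.0)

    def test_groups_follow_score_sign(self):
        high, low = dichotomize_by_score(self.clf(), self.x)
        assert sorted(high) == ["s0", "s1"] and sorted(low) == ["s2", "s3"]

    def test_threshold_above_all_scores_warns(self):
        with pytest.warns(UserWarning, match="one side"):
            high, low = dichotomize_by_score(self.clf(), self.x, threshold=100.0)
        assert high == [] and len(low) == 4
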