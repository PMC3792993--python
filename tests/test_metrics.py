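"""ROC/AUC, NRI, AUC-gain testing, and the cohort-characteristics statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import liporisk as lr
from liporisk.metrics import chi2_proportions_p

from conftest import build_cohort


def scored_instances():
    return st.integers(2, 50).flatmap(
        lambda n: st.tuples(
            st.lists(
                st.integers(-5, 5).map(float), min_size=n, max_size=n
            ),
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda t: 0 < sum(t) < len(t)
            ),
        )
    )


class TestAUC:
    def test_perfect_separation(self):
        assert lr.auc([2, 3, 0, 1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert lr.auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_pair_count_example(self):
        # events {3,1}, nonevents {2,0}: concordant (3,2),(3,0),(1,0) of 4 pairs
        assert lr.auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            lr.auc([1, 2], [1, 1])

    def test_reversing_scores_complements(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=30)
        t = rng.integers(0, 2, 30)
        t[0], t[1] = 0, 1
        assert lr.auc(-s, t) == pytest.approx(1 - lr.auc(s, t), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(scored_instances())
    def test_rank_sum_equals_trapezoid(self, inst):
        """Mann-Whitney identity: midrank AUC == trapezoidal ROC area."""
        scores, truth = inst
        curve = lr.roc_curve(scores, truth)
        assert curve.auc == pytest.approx(lr.auc(scores, truth), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(scored_instances())
    def test_roc_curve_invariants(self, inst):
        scores, truth = inst
        c = lr.roc_curve(scores, truth)
        assert (np.diff(c.tpr) >= 0).all() and (np.diff(c.fpr) >= 0).all()
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(c.thresholds) < 0).all()

    def test_perfect_separator_passes_top_left(self):
        c = lr.roc_curve([2, 3, 0, 1], [1, 1, 0, 0])
        assert any(f == 0 and t == 1 for f, t in zip(c.fpr, c.tpr))


class TestConfusionMetrics:
    def test_threshold_below_all(self):
        m = lr.confusion_metrics([1, 2, 3, 4], [1, 1, 0, 0], threshold=-10)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_per_group_accuracy(self):
        m = lr.confusion_metrics(
            [1, -1, -1], [1, 1, 0], 0.0, groups=["T2D", "IGT", "NGT"]
        )
        acc = m["per_group_accuracy"]
        assert acc == {"T2D": 1.0, "IGT": 0.0, "NGT": 1.0}

    def test_empty_group_reports_nan(self):
        m = lr.confusion_metrics([1, -1], [1, 0], 0.0, groups=["IGT", "NGT"])
        assert np.isnan(m["per_group_accuracy"]["T2D"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scored_instances(), st.floats(-3, 3))
    def test_correct_count_identity(self, inst, threshold):
        scores, truth = inst
        m = lr.confusion_metrics(scores, truth, threshold)
        n1 = sum(truth)
        n0 = len(truth) - n1
        total_correct = sum(
            (s >= threshold) == bool(t) for s, t in zip(scores, truth)
        )
        assert m["sensitivity"] * n1 + m["specificity"] * n0 == pytest.approx(
            total_correct
        )


class TestNRI:
    def test_no_change_is_zero(self):
        pred = [1, 0, 1, 0]
        truth = [1, 1, 0, 0]
        r = lr.nri(pred, pred, truth)
        assert r.nri == 0
        assert (r.up_events, r.down_events, r.up_nonevents, r.down_nonevents) == (0,) * 4

    def test_hand_counted_example(self):
        # 10 events: 2 up, 1 down; 20 nonevents: 1 up, 3 down
        truth = [1] * 10 + [0] * 20
        old = [0, 0, 1, 1, 1, 1, 1, 1, 1, 1] + [0] * 16 + [1, 1, 1, 1]
        new = [1, 1, 0, 1, 1, 1, 1, 1, 1, 1] + [1] + [0] * 15 + [0, 0, 0, 1]
        r = lr.nri(old, new, truth)
        assert (r.up_events, r.down_events) == (2, 1)
        assert (r.up_nonevents, r.down_nonevents) == (1, 3)
        assert r.nri == pytest.approx((2 - 1) / 10 + (3 - 1) / 20)  # 0.2

    def test_antisymmetry_and_bounds_random(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(4, 40)
            truth = rng.integers(0, 2, n)
            truth[0], truth[1] = 1, 0
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            r = lr.nri(a, b, truth)
            s = lr.nri(b, a, truth)
            assert r.nri == pytest.approx(-s.nri, abs=1e-15)
            assert -1 <= r.event_component <= 1
            assert -1 <= r.nonevent_component <= 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="align"):
            lr.nri([1, 0], [1], [1, 0])


class TestAUCGain:
    def test_identical_samples(self):
        a = np.linspace(0.6, 0.8, 20)
        res = lr.auc_gain_test(a, a)
        assert res["gain"] == 0 and res["p_value"] >= 0.999

    def test_constant_shift(self):
        a = np.linspace(0.6, 0.8, 600)
        res = lr.auc_gain_test(a, a + 0.05)
        assert res["gain"] == pytest.approx(0.05, abs=1e-12)

    def test_power_of_paired_test(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.70, 0.01, 600)
        b = rng.normal(0.75, 0.01, 600)
        res = lr.auc_gain_test(a, b)
        assert res["p_value"] < 0.001
        assert res["gain"] == pytest.approx(0.05, abs=0.005)

    def test_wilcoxon_alternative(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.70, 0.01, 200)
        res = lr.auc_gain_test(a, a + rng.normal(0.02, 0.005, 200), method="wilcoxon")
        assert res["p_value"] < 0.001

    def test_too_few_iterations(self):
        with pytest.raises(ValueError, match="2 iterations"):
            lr.auc_gain_test([0.7], [0.8])


class TestMannWhitney:
    def test_spec_example_exact(self):
        # U = 0, two-sided exact p over C(6,3)=20 assignments
        assert lr.mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_matches_scipy_all_small_sizes(self):
        rng = np.random.default_rng(0)
        for n in range(1, 8):
            for m in range(1, 9 - n):
                for _ in range(5):
                    x = rng.normal(size=n)
                    y = rng.normal(size=m)
                    ours = lr.mann_whitney_p(x, y)
                    ref = stats.mannwhitneyu(
                        x, y, alternative="two-sided", method="exact"
                    ).pvalue
                    assert ours == pytest.approx(ref, abs=1e-12)

    def test_identical_constant_groups(self):
        assert lr.mann_whitney_p([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        p = lr.mann_whitney_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force_bh(p):
        """Independent step-up oracle: adj[i] = min over k with p(k) >= p(i)
        of p(k) * m / rank(k), computed by exhaustive search."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for i in range(m):
            rank_i = int(np.flatnonzero(order == i)[0])
            adj[i] = min(min(p[order[k]] * m / (k + 1) for k in range(rank_i, m)), 1.0)
        return adj

    def test_single_p_unchanged(self):
        assert lr.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        assert np.allclose(lr.benjamini_hochberg([0.2] * 5), 0.2)

    def test_hand_examples(self):
        assert np.allclose(
            lr.benjamini_hochberg([0.005, 0.04, 0.9]), [0.015, 0.06, 0.9]
        )
        assert np.allclose(
            lr.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            assert np.allclose(lr.benjamini_hochberg(p), self.brute_force_bh(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 20)
        adj = lr.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr.benjamini_hochberg([0.5, 1.2])


class TestCohortCharacteristics:
    def test_identical_groups_all_adjusted_p_one(self):
        lipids = {"DG_001": [1.0, 2.0, 3.0, 4.0] * 2}
        rf = {"age": [50, 60, 70, 80] * 2, "sex": [0, 1, 0, 1] * 2}
        t = build_cohort(["T2D", "IGT", "T2D", "IGT", "NGT", "NGT", "NGT", "NGT"], lipids, rf)
        # make every continuous risk factor identical between groups
        for col in t.risk_factor_names:
            t.data[col] = list(t.data[col][:4]) * 2
        out = lr.cohort_characteristics(t)
        assert (out["p_adjusted"] == 1.0).all()

    def test_known_shifted_variable_has_smallest_p(self):
        rng = np.random.default_rng(7)
        n1, n0 = 40, 80
        rf = {c: rng.normal(0, 1, n1 + n0) for c in
              ("age", "systolic_bp", "waist", "total_cholesterol", "hdl_c", "triglycerides")}
        rf["hba1c"] = np.r_[rng.normal(2.0, 1, n1), rng.normal(0, 1, n0)]
        rf["sex"] = rng.integers(0, 2, n1 + n0)
        t = build_cohort(["IGT"] * n1 + ["NGT"] * n0, {"DG_001": np.ones(n1 + n0)}, rf)
        out = lr.cohort_characteristics(t).set_index("variable")
        assert out["p_adjusted"].idxmin() == "hba1c"

    def test_chi2_degenerate_table(self):
        assert chi2_proportions_p([1, 1, 1], [1, 1]) == 1.0

    def test_layout(self, tiny_cohort):
        out = lr.cohort_characteristics(tiny_cohort)
        assert list(out.columns) == ["variable", "at_risk", "ngt", "p_value", "p_adjusted"]
        assert len(out) == 8
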