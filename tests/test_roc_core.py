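"""ROC construction, AUC estimators, Youden selection and DeLong's test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ppv_greyzone import roc_core as rc


class TestEmpiricalRoc:
    @pytest.mark.parametrize(
        "pos, neg, expected_auc",
        [
            ([2, 3], [0, 1], 1.0),
            ([1, 1], [1, 1], 0.5),
            ([1, 3], [0, 2], 0.75),
        ],
    )
    def test_auc_small_instances(self, pos, neg, expected_auc):
        values = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg), bool)
        roc = rc.empirical_roc(values, labels)
        assert roc.auc == pytest.approx(expected_auc)
        assert rc.auc_brute_force(values, labels) == pytest.approx(expected_auc)

    def test_curve_invariants(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 15, 60).astype(float)
        labels = rng.random(60) < 0.5
        roc = rc.empirical_roc(values, labels)
        assert (np.diff(roc.thresholds) > 0).all()
        assert (np.diff(roc.se) <= 0).all() and (np.diff(roc.sp) >= 0).all()
        assert 0 <= roc.auc <= 1
        assert roc.se.min() >= 0 and roc.se.max() <= 1

    def test_degenerate_labels(self):
        with pytest.raises(rc.DegenerateLabelsError):
            rc.empirical_roc([1, 2, 3], [True, True, True])

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(10, 120)
            values = rng.integers(0, 10, n).astype(float)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            roc = rc.empirical_roc(values, labels)
            assert roc.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_orientation_symmetry_without_ties(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        a = rc.empirical_roc(values, labels, rc.POSITIVE).auc
        b = rc.empirical_roc(values, labels, rc.NEGATIVE).auc
        assert a + b == pytest.approx(1.0)

    def test_trapezoid_equals_mann_whitney(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 80)
            values = rng.integers(0, 6, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            for orient in (rc.POSITIVE, rc.NEGATIVE):
                roc = rc.empirical_roc(values, labels, orient)
                assert roc.trapezoid_auc() == pytest.approx(roc.auc, abs=1e-12)


class TestYouden:
    def test_tied_maxima_resolve_toward_sensitivity(self):
        values = np.array([1, 3, 0, 2], float)
        labels = np.array([1, 1, 0, 0], bool)
        best = rc.youden_threshold(rc.empirical_roc(values, labels))
        assert best.threshold == 1.0
        assert best.youden_j == pytest.approx(0.5)

    def test_perfect_separation(self):
        roc = rc.empirical_roc([5, 6, 1, 2], [1, 1, 0, 0])
        best = rc.youden_threshold(roc)
        assert best.youden_j == pytest.approx(1.0)
        assert best.threshold == 5.0  # smallest separating candidate

    def test_uninformative_marker_returns_smallest_candidate(self):
        roc = rc.empirical_roc([5, 5, 5, 5], [1, 0, 1, 0])
        best = rc.youden_threshold(roc)
        assert best.youden_j == pytest.approx(0.0)
        assert best.threshold == roc.thresholds[0] == 4.0  # sentinel below min

    def test_binormal_threshold_converges_to_midpoint(self):
        rng = np.random.default_rng(5)
        n = 10**5
        values = np.concatenate([rng.normal(2, 1, n // 2), rng.normal(0, 1, n // 2)])
        labels = np.repeat([True, False], n // 2)
        best = rc.youden_threshold(rc.empirical_roc(values, labels))
        assert best.threshold == pytest.approx(1.0, abs=0.1)


class TestLikelihoodRatios:
    @pytest.mark.parametrize(
        "se, sp, lr_pos, lr_neg",
        [(0.63, 0.71, 2.17, 0.52), (0.70, 0.67, 2.12, 0.45), (0.5, 0.5, 1.0, 1.0)],
    )
    def test_values(self, se, sp, lr_pos, lr_neg):
        lp, ln = rc.likelihood_ratios(se, sp)
        assert round(lp, 2) == lr_pos
        assert round(ln, 2) == lr_neg

    def test_flagged_infinities(self):
        with pytest.warns(UserWarning):
            lp, _ = rc.likelihood_ratios(0.8, 1.0)
        assert np.isinf(lp)
        with pytest.warns(UserWarning):
            _, ln = rc.likelihood_ratios(0.8, 0.0)
        assert np.isinf(ln)


class TestDeLong:
    def test_self_comparison(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        res = rc.delong_compare(values, values, labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_swap_symmetry_and_nonnegative_variance(self):
        rng = np.random.default_rng(7)
        labels = rng.random(100) < 0.5
        a = rng.normal(size=100) + labels
        b = rng.normal(size=100) + 0.5 * labels
        r1 = rc.delong_compare(a, b, labels)
        r2 = rc.delong_compare(b, a, labels)
        assert r1.variance >= 0
        assert r1.p == pytest.approx(r2.p)
        assert r1.delta == pytest.approx(-r2.delta)

    def test_small_pairing_warns(self):
        labels = np.array([1, 1, 0, 0, 1, 0], bool)
        with pytest.warns(rc.InsufficientPairingWarning):
            rc.delong_compare([1, 2, 0, 1, 3, 0], [2, 1, 0, 2, 2, 1], labels)

    def test_variance_tracks_binomial_scale(self):
        """DeLong variance of a single AUC is close to the Hanley-McNeil
        large-sample approximation on smooth data."""
        rng = np.random.default_rng(8)
        n = 2000
        values = np.concatenate([rng.normal(1, 1, n // 2), rng.normal(0, 1, n // 2)])
        labels = np.repeat([True, False], n // 2)
        auc, var = rc.auc_variance(values, labels)
        assert auc == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)), abs=0.03)
        assert 0 < var < 1e-3


@given(st.data())
def test_brute_force_agrees_on_random_instances(data):
    m = data.draw(st.integers(1, 12))
    n = data.draw(st.integers(1, 12))
    pos = data.draw(st.lists(st.integers(0, 6), min_size=m, max_size=m))
    neg = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
    values = np.array(pos + neg, float)
    labels = np.array([1] * m + [0] * n, bool)
    roc = rc.empirical_roc(values, labels)
    assert roc.auc == pytest.approx(rc.auc_brute_force(values, labels), abs=1e-12)
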