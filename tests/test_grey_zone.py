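"""Two-step grey-zone determination: bootstrap CIs, tolerance zones,
retain-wider combination, membership."""

import numpy as np
import pytest

from ppv_greyzone import grey_zone as gzm
from ppv_greyzone import roc_core as rc
from ppv_greyzone import synthetic_cohort as sc
from ppv_greyzone.grey_zone import (
    BootstrapConfig,
    GreyZone,
    bootstrap_thresholds,
    combine_grey_zone,
    compare_membership,
    membership,
    tolerance_zone,
)


def _binormal(rng, n, mu1=2.0, mu0=0.0, sd=1.0):
    values = np.concatenate([rng.normal(mu1, sd, n // 2), rng.normal(mu0, sd, n - n // 2)])
    labels = np.repeat([True, False], [n // 2, n - n // 2])
    return values, labels


class TestToleranceZone:
    def test_perfect_separation_is_empty(self):
        roc = rc.empirical_roc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        lo, hi = tolerance_zone(roc)
        assert lo >= hi

    def test_binormal_bounds(self):
        rng = np.random.default_rng(10)
        values, labels = _binormal(rng, 40_000)
        roc = rc.empirical_roc(values, labels)
        lo, hi = tolerance_zone(roc, 0.10)
        assert lo == pytest.approx(2 - 1.2816, abs=0.05)
        assert hi == pytest.approx(1.2816, abs=0.05)

    def test_nonempty_zone_excludes_jointly_tolerant_thresholds(self):
        """If the zone is non-empty, no candidate threshold (and hence not
        the Youden threshold) attains Se >= 90% and Sp >= 90% together."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(30, 200))
            values = rng.integers(0, 20, n).astype(float)
            labels = rng.random(n) < 0.5
            labels += values > 12  # some signal
            labels = labels.astype(bool)
            if labels.all() or not labels.any():
                continue
            roc = rc.empirical_roc(values, labels)
            lo, hi = tolerance_zone(roc)
            if lo < hi:
                assert not ((roc.se >= 0.9) & (roc.sp >= 0.9)).any()

    def test_monotone_shrinkage_in_tolerance(self):
        rng = np.random.default_rng(12)
        values, labels = _binormal(rng, 2000)
        roc = rc.empirical_roc(values, labels)
        lo1, hi1 = tolerance_zone(roc, 0.10)
        lo2, hi2 = tolerance_zone(roc, 0.20)
        assert lo2 >= lo1 and hi2 <= hi1

    def test_unreachable_tolerance_warns(self):
        # overlapping coarse data where no cut reaches 90% specificity
        values = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], float)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        roc = rc.empirical_roc(values, labels)
        with pytest.warns(gzm.UnreachableToleranceWarning):
            tolerance_zone(roc, 0.10)

    def test_negative_orientation_mirrors(self):
        rng = np.random.default_rng(13)
        values, labels = _binormal(rng, 20_000)
        pos = tolerance_zone(rc.empirical_roc(values, labels, rc.POSITIVE))
        neg = tolerance_zone(rc.empirical_roc(-values, labels, rc.NEGATIVE))
        assert neg[0] == pytest.approx(-pos[1], abs=1e-9)
        assert neg[1] == pytest.approx(-pos[0], abs=1e-9)


class TestCombine:
    @pytest.mark.parametrize(
        "ci, tol, expected, source",
        [
            ((9, 14), (4, 17), (4, 17), "tolerance_zone"),
            ((2, 20), (8, 12), (2, 20), "bootstrap_ci"),
            ((5, 6), (10, 9), (5, 6), "bootstrap_ci"),  # empty tolerance zone
        ],
    )
    def test_retain_wider(self, ci, tol, expected, source):
        zone = combine_grey_zone(ci, tol)
        assert (zone.lower, zone.upper) == expected
        assert zone.source == source

    def test_width_is_max_of_widths(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            ci = tuple(np.sort(rng.normal(size=2)))
            tol = tuple(np.sort(rng.normal(size=2)))
            zone = combine_grey_zone(ci, tol)
            assert zone.width == pytest.approx(max(ci[1] - ci[0], tol[1] - tol[0]))

    def test_equal_widths_prefer_tolerance(self):
        assert combine_grey_zone((0, 5), (10, 15)).source == "tolerance_zone"


class TestMembership:
    def test_extremes(self):
        full = GreyZone(0, 100, "tolerance_zone")
        out = GreyZone(200, 300, "tolerance_zone")
        v = [3, 5, 10, 18]
        assert membership(v, full) == 1.0
        assert membership(v, out) == 0.0

    def test_counts_closed_bounds(self):
        zone = GreyZone(4, 17, "tolerance_zone")
        assert membership([3, 5, 10, 18], zone) == 0.5
        assert membership([4, 17, 3, 18], zone) == 0.5

    def test_empty_zone_rejected(self):
        with pytest.raises(ValueError):
            membership([1, 2], GreyZone(5, 4, "bootstrap_ci", empty=True))


class TestCompareMembership:
    def test_equal_proportions(self):
        assert compare_membership(62, 100, 62, 100) == 1.0

    def test_published_counts_significant(self):
        # 62% vs 71% at the study's group sizes
        assert compare_membership(345, 556, 288, 406) < 0.01

    def test_invalid(self):
        with pytest.raises(ValueError):
            compare_membership(1, 0, 1, 2)


class TestBootstrap:
    def test_deterministic(self):
        rng = np.random.default_rng(15)
        values, labels = _binormal(rng, 200)
        cfg = BootstrapConfig(200, seed=9)
        a = bootstrap_thresholds(values, labels, config=cfg)
        b = bootstrap_thresholds(values, labels, config=cfg)
        assert np.array_equal(a.best_thresholds, b.best_thresholds)
        assert a.threshold_ci == b.threshold_ci

    def test_perfect_separation_ci_within_gap(self):
        values = np.array([10.0] * 10 + [0.0] * 10)
        labels = np.repeat([True, False], 10)
        res = bootstrap_thresholds(values, labels, config=BootstrapConfig(300, 1))
        lo, hi = res.threshold_ci
        assert 0 < lo <= hi <= 10
        assert (res.aucs == 1.0).all()

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(gzm.DegenerateCohortError):
            bootstrap_thresholds([1, 2, 3, 4, 5, 6], [1, 0, 0, 0, 0, 0])

    def test_auc_median_near_full_sample(self):
        rng = np.random.default_rng(16)
        values, labels = _binormal(rng, 300)
        full = rc.empirical_roc(values, labels).auc
        res = bootstrap_thresholds(values, labels, config=BootstrapConfig(5000, 2))
        assert res.auc_median == pytest.approx(full, abs=0.005)

    def test_negative_orientation_threshold_scale(self):
        rng = np.random.default_rng(17)
        values, labels = _binormal(rng, 400)
        pos = bootstrap_thresholds(values, labels, rc.POSITIVE, BootstrapConfig(300, 3))
        neg = bootstrap_thresholds(-values, labels, rc.NEGATIVE, BootstrapConfig(300, 3))
        assert np.allclose(np.sort(-neg.best_thresholds), np.sort(pos.best_thresholds))


class TestParameterRecovery:
    def test_grey_zone_tracks_analytic_tolerance_zone(self):
        """Cohorts regenerated at the study conditions recover grey zones
        that overlap, and centre on, the tolerance zone of the generating
        truncated distributions."""
        cfg = sc.default_config()
        _, (an_lo, an_hi) = sc.truncated_marker_oracle(cfg, "ppv", n_draws=300_000)
        lowers, uppers = [], []
        for rep in range(25):
            cfg.seed = 100 + rep
            df = sc.generate_cohort(cfg).df
            ok = df["ppv_pct"].notna() & df["responder"].notna()
            values = df.loc[ok, "ppv_pct"].to_numpy()
            labels = df.loc[ok, "responder"].astype(bool).to_numpy()
            roc = rc.empirical_roc(values, labels)
            tz = tolerance_zone(roc)
            boot = bootstrap_thresholds(values, labels, config=BootstrapConfig(500, rep))
            zone = combine_grey_zone(boot.threshold_ci, tz)
            assert zone.lower < an_hi and zone.upper > an_lo  # overlap
            lowers.append(zone.lower)
            uppers.append(zone.upper)
        assert np.median(lowers) == pytest.approx(an_lo, abs=2.0)
        assert np.median(uppers) == pytest.approx(an_hi, abs=2.0)


class TestAlternativeModes:
    def test_bootstrap_mean_curve_smooths_but_agrees(self):
        rng = np.random.default_rng(18)
        values, labels = _binormal(rng, 600)
        mean_curve = gzm.bootstrap_mean_curve(
            values, labels, config=BootstrapConfig(200, 6)
        )
        plain = rc.empirical_roc(values, labels)
        assert mean_curve.auc == pytest.approx(plain.auc, abs=0.02)
        assert (np.diff(mean_curve.se) <= 1e-12).all()
        lo, hi = tolerance_zone(mean_curve)
        lo0, hi0 = tolerance_zone(plain)
        assert lo == pytest.approx(lo0, abs=0.3)
        assert hi == pytest.approx(hi0, abs=0.3)

    def test_paired_membership_mcnemar(self):
        a = np.array([True] * 30 + [False] * 30)
        assert gzm.compare_membership_paired(a, a) == 1.0
        b = np.array([True] * 55 + [False] * 5)  # 25 discordant, all one way
        assert gzm.compare_membership_paired(a, b) < 0.001

    def test_midpoint_candidate_mode(self):
        values = np.array([1.0, 3.0, 0.0, 2.0])
        labels = np.array([1, 1, 0, 0], bool)
        roc = rc.empirical_roc(values, labels, candidates="midpoint")
        assert roc.auc == pytest.approx(0.75)  # AUC independent of grid
        assert 0.5 in roc.thresholds and 1.5 in roc.thresholds
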