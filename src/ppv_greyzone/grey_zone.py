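"""Two-step grey-zone determination for a diagnostic marker.

Step 1: bootstrap the cohort (patient-level resampling with replacement,
B = 1000 by default), record the Youden-optimal threshold in every
resample, and take the 2.5th/97.5th percentiles as the 95% CI of the best
threshold. Step 2: on the original sample's Se/Sp curves, find the
interval of marker values that cannot be read with a 10% diagnostic
tolerance — between the last threshold keeping Se >= 90% (rule-out bound)
and the first keeping Sp >= 90% (rule-in bound). The grey zone is
whichever of the two intervals is wider; values inside it are
inconclusive for fluid responsiveness.

The bootstrap engine is shared with the cost-weighted analysis: the
Youden criterion is the special case of per-patient misclassification
costs 1/n_pos for false negatives and 1/n_neg for false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .roc_core import NEGATIVE, POSITIVE, RocCurve, _as_arrays

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "GreyZone",
    "DegenerateCohortError",
    "UnreachableToleranceWarning",
    "bootstrap_thresholds",
    "tolerance_zone",
    "combine_grey_zone",
    "membership",
    "compare_membership",
    "compare_membership_paired",
    "bootstrap_mean_curve",
    "scan_optimal_threshold",
]


class DegenerateCohortError(ValueError):
    """Too few members of one outcome class to resample meaningfully."""


class UnreachableToleranceWarning(UserWarning):
    """No candidate threshold attains the requested Se or Sp."""


@dataclass
class BootstrapConfig:
    """Patient-level bootstrap settings (resample unit: patient)."""

    n_resamples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class BootstrapResult:
    best_thresholds: np.ndarray  # length B, original marker scale
    aucs: np.ndarray  # length B
    threshold_ci: tuple[float, float]  # 2.5th / 97.5th percentiles
    auc_median: float
    auc_ci: tuple[float, float]
    n_degenerate_redrawn: int


@dataclass
class GreyZone:
    """An inconclusive interval of marker values, with provenance."""

    lower: float
    upper: float
    source: str  # "bootstrap_ci" | "tolerance_zone"
    tolerance: float = 0.10
    membership_fraction: Optional[float] = None
    empty: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower


# ---------------------------------------------------------------------------
# threshold scan engine (rows = resamples)

def _scan_rows(vals: np.ndarray, fn_cost: np.ndarray, fp_cost: np.ndarray):
    """Minimize total misclassification cost over candidate thresholds,
    rowwise.

    ``vals`` is (B, n); ``fn_cost`` is the cost incurred by patient i if
    called negative while positive (0 for controls); ``fp_cost`` the cost
    if called positive while negative (0 for cases). Call rule: value >=
    threshold. Candidates are the row's unique values plus a sentinel
    below the minimum; cost ties resolve to the smallest candidate.

    Returns (best threshold per row, best cost per row).
    """
    order = np.argsort(vals, axis=1, kind="stable")
    sv = np.take_along_axis(vals, order, axis=1)
    sfn = np.take_along_axis(fn_cost, order, axis=1)
    sfp = np.take_along_axis(fp_cost, order, axis=1)
    total_fp = sfp.sum(axis=1, keepdims=True)
    zeros = np.zeros((vals.shape[0], 1))
    cum_fn = np.concatenate([zeros, np.cumsum(sfn, axis=1)[:, :-1]], axis=1)
    cum_fp = np.concatenate([zeros, np.cumsum(sfp, axis=1)[:, :-1]], axis=1)
    # cost at threshold = sv[:, k]: all values below k called negative
    cost = cum_fn + (total_fp - cum_fp)
    first = np.concatenate(
        [np.ones((vals.shape[0], 1), bool), sv[:, 1:] != sv[:, :-1]], axis=1
    )
    cost = np.where(first, cost, np.inf)
    # sentinel (call everyone positive) sits before the first candidate
    cost_full = np.concatenate([total_fp, cost], axis=1)
    k = np.argmin(cost_full, axis=1)  # first minimum -> smallest candidate
    rows = np.arange(vals.shape[0])
    best = np.where(k == 0, sv[:, 0] - 1.0, sv[rows, np.maximum(k - 1, 0)])
    best_cost = cost_full[rows, k]
    return best, best_cost


def scan_optimal_threshold(
    values,
    labels,
    orientation: str = POSITIVE,
    fn_cost=None,
    fp_cost=None,
) -> float:
    """Single-sample cost-minimizing threshold (Youden when costs omitted)."""
    v, y = _as_arrays(values, labels)
    s = v if orientation == POSITIVE else -v
    m = y.sum()
    if fn_cost is None:
        fn = y / m
        fp = (~y) / (y.size - m)
    else:
        fn = np.where(y, np.asarray(fn_cost, float), 0.0)
        fp = np.where(~y, np.asarray(fp_cost, float), 0.0)
    best, _ = _scan_rows(s[None, :], fn[None, :], fp[None, :])
    t = best[0]
    return float(t if orientation == POSITIVE else -t)


def _rowwise_auc(vals: np.ndarray, labs: np.ndarray) -> np.ndarray:
    r = stats.rankdata(vals, axis=1)
    m = labs.sum(axis=1)
    n = vals.shape[1] - m
    return ((r * labs).sum(axis=1) - m * (m + 1) / 2) / (m * n)


def bootstrap_thresholds(
    values,
    labels,
    orientation: str = POSITIVE,
    config: Optional[BootstrapConfig] = None,
    fn_cost=None,
    fp_cost=None,
) -> BootstrapResult:
    """Bootstrap distribution of optimal thresholds and AUCs.

    Draws B patient-level resamples with replacement; each records its
    Youden-optimal (or cost-optimal, when per-patient costs are given)
    threshold and its Mann-Whitney AUC. Resamples that lose an outcome
    class are redrawn so B stays fixed; the redraw count is reported.
    """
    config = config or BootstrapConfig()
    v, y = _as_arrays(values, labels)
    if y.sum() < 5 or (~y).sum() < 5:
        raise DegenerateCohortError(
            f"need >= 5 patients per class to bootstrap (got {int(y.sum())} / {int((~y).sum())})"
        )
    s = v if orientation == POSITIVE else -v
    n = s.size
    B = config.n_resamples
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(B, n))
    n_redrawn = 0
    while True:
        m_rows = y[idx].sum(axis=1)
        bad = (m_rows == 0) | (m_rows == n)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    vals = s[idx]
    labs = y[idx]
    m_rows = labs.sum(axis=1)[:, None]
    if fn_cost is None:
        fn = labs / m_rows
        fp = (~labs) / (n - m_rows)
    else:
        fn = np.where(labs, np.asarray(fn_cost, float)[idx], 0.0)
        fp = np.where(~labs, np.asarray(fp_cost, float)[idx], 0.0)
    best, _ = _scan_rows(vals, fn, fp)
    aucs = _rowwise_auc(vals, labs)
    if orientation == NEGATIVE:
        best = -best
    lo, hi = np.percentile(best, [2.5, 97.5])
    alo, ahi = np.percentile(aucs, [2.5, 97.5])
    return BootstrapResult(
        best_thresholds=best,
        aucs=aucs,
        threshold_ci=(float(lo), float(hi)),
        auc_median=float(np.median(aucs)),
        auc_ci=(float(alo), float(ahi)),
        n_degenerate_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# step 2: diagnostic-tolerance zone

def tolerance_zone(roc: RocCurve, tolerance: float = 0.10) -> tuple[float, float]:
    """Bounds of the inconclusive zone at the given diagnostic tolerance.

    For a positively oriented marker: the lower bound is the largest
    candidate threshold still ruling out responsiveness with Se >= 1 -
    tolerance; the upper bound the smallest candidate ruling it in with
    Sp >= 1 - tolerance. Values strictly between the bounds satisfy
    neither. Mirrored for negative orientation. When a bound is
    unreachable the data extreme is returned with an
    :class:`UnreachableToleranceWarning`.
    """
    if not 0 < tolerance < 0.5:
        raise ValueError("tolerance must be in (0, 0.5)")
    target = 1.0 - tolerance - 1e-12
    ok_se = roc.se >= target
    ok_sp = roc.sp >= target
    if roc.orientation == POSITIVE:
        # sentinel (index 0) always has Se = 1
        i = int(np.flatnonzero(ok_se)[-1])
        if i == 0:
            warnings.warn(
                f"no observed threshold attains Se >= {1 - tolerance:.2f} for "
                f"{roc.marker or 'marker'}; using the data minimum",
                UnreachableToleranceWarning,
                stacklevel=2,
            )
            lower = roc.data_min()
        else:
            lower = float(roc.thresholds[i])
        js = np.flatnonzero(ok_sp)
        if js.size == 0:
            warnings.warn(
                f"no threshold attains Sp >= {1 - tolerance:.2f} for "
                f"{roc.marker or 'marker'}; using the data maximum",
                UnreachableToleranceWarning,
                stacklevel=2,
            )
            upper = roc.data_max()
        else:
            upper = float(roc.thresholds[int(js[0])])
    else:
        # thresholds ascending; Se non-decreasing, sentinel is last
        js = np.flatnonzero(ok_se)
        i = int(js[0])
        if i == roc.thresholds.size - 1:
            warnings.warn(
                f"no observed threshold attains Se >= {1 - tolerance:.2f} for "
                f"{roc.marker or 'marker'}; using the data maximum",
                UnreachableToleranceWarning,
                stacklevel=2,
            )
            upper = roc.data_max()
        else:
            upper = float(roc.thresholds[i])
        ks = np.flatnonzero(ok_sp)
        if ks.size == 0:
            warnings.warn(
                f"no threshold attains Sp >= {1 - tolerance:.2f} for "
                f"{roc.marker or 'marker'}; using the data minimum",
                UnreachableToleranceWarning,
                stacklevel=2,
            )
            lower = roc.data_min()
        else:
            lower = float(roc.thresholds[int(ks[-1])])
    return lower, upper


def combine_grey_zone(
    threshold_ci: tuple[float, float],
    tol_zone: tuple[float, float],
    tolerance: float = 0.10,
) -> GreyZone:
    """Retain the wider of the bootstrap threshold CI and the tolerance zone.

    Equal widths resolve to the tolerance zone. An interval with
    non-positive width counts as empty; if both are empty the zone is
    flagged empty.
    """
    ci_lo, ci_hi = threshold_ci
    tz_lo, tz_hi = tol_zone
    ci_w = ci_hi - ci_lo
    tz_w = tz_hi - tz_lo
    if ci_w > tz_w:
        lower, upper, source = ci_lo, ci_hi, "bootstrap_ci"
    else:
        lower, upper, source = tz_lo, tz_hi, "tolerance_zone"
    return GreyZone(
        lower=float(lower),
        upper=float(upper),
        source=source,
        tolerance=tolerance,
        empty=bool(upper <= lower),
    )


def membership(values, zone: GreyZone) -> float:
    """Fraction of complete-case marker values inside [lower, upper]."""
    if zone.empty:
        raise ValueError("membership is undefined for an empty grey zone")
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no complete-case values")
    return float(np.mean((v >= zone.lower) & (v <= zone.upper)))


def bootstrap_mean_curve(
    values,
    labels,
    orientation: str = POSITIVE,
    config: Optional[BootstrapConfig] = None,
) -> RocCurve:
    """Bootstrap-averaged Se/Sp curves on the observed threshold grid.

    Alternative input for :func:`tolerance_zone` (sensitivity-analysis
    mode); the default pipeline uses the single original-sample curves.
    """
    from .roc_core import empirical_roc

    config = config or BootstrapConfig()
    base = empirical_roc(values, labels, orientation=orientation)
    v, y = _as_arrays(values, labels)
    s = v if orientation == POSITIVE else -v
    grid = base.thresholds if orientation == POSITIVE else -base.thresholds[::-1]
    n = s.size
    rng = np.random.default_rng(config.seed)
    se_sum = np.zeros(grid.size)
    sp_sum = np.zeros(grid.size)
    auc_sum = 0.0
    done = 0
    while done < config.n_resamples:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        m = int(yb.sum())
        if m == 0 or m == n:
            continue
        sb = s[idx]
        pos = np.sort(sb[yb])
        neg = np.sort(sb[~yb])
        se_sum += 1.0 - np.searchsorted(pos, grid, side="left") / m
        sp_sum += np.searchsorted(neg, grid, side="left") / (n - m)
        auc_sum += _mann_whitney_auc_1d(sb, yb)
        done += 1
    se = se_sum / done
    sp = sp_sum / done
    if orientation == NEGATIVE:
        se, sp = se[::-1], sp[::-1]
    return RocCurve(
        marker=base.marker,
        orientation=orientation,
        thresholds=base.thresholds,
        se=se,
        sp=sp,
        auc=auc_sum / done,
        n_pos=base.n_pos,
        n_neg=base.n_neg,
    )


def _mann_whitney_auc_1d(v: np.ndarray, y: np.ndarray) -> float:
    r = stats.rankdata(v)
    m = int(y.sum())
    return float((r[y].sum() - m * (m + 1) / 2) / (m * (y.size - m)))


def compare_membership_paired(in_zone_a, in_zone_b) -> float:
    """McNemar-style paired comparison of grey-zone membership.

    Takes per-patient booleans for the two markers on the same patients
    (complete cases for both); tests the discordant counts with the
    exact binomial McNemar test. Alternative to the independent-
    proportions default.
    """
    a = np.asarray(in_zone_a, bool)
    b = np.asarray(in_zone_b, bool)
    if a.shape != b.shape:
        raise ValueError("paired membership vectors must align")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    if n01 + n10 == 0:
        return 1.0
    return float(stats.binomtest(n10, n10 + n01, 0.5).pvalue)


def compare_membership(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Two-sided two-proportion chi-square test (no continuity correction).

    Used to compare grey-zone occupancy between two markers; the two
    fractions are treated as independent proportions.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k_a / n_a, k_b / n_b
    pooled = (k_a + k_b) / (n_a + n_b)
    var = pooled * (1 - pooled) * (1 / n_a + 1 / n_b)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
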