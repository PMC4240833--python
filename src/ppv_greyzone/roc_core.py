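"""Empirical ROC analysis for a continuous marker against a binary outcome.

Implements ROC construction over observed candidate thresholds, the
Mann-Whitney AUC (ties counted 1/2), Youden-index threshold selection,
likelihood ratios, an all-pairs brute-force AUC oracle, and DeLong's
placement-value test for comparing two correlated AUCs measured on the
same patients.

Orientation conventions
-----------------------
``higher_predicts_responder`` (e.g. PPV): a patient is called positive
when marker >= threshold. ``lower_predicts_responder`` (e.g. CVP): called
positive when marker <= threshold. Curves are always stored with strictly
increasing thresholds on the original marker scale; a sentinel threshold
one unit outside the data range represents the "call everyone positive"
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "RocCurve",
    "ThresholdStats",
    "DeLongResult",
    "DegenerateLabelsError",
    "InsufficientPairingWarning",
    "empirical_roc",
    "youden_threshold",
    "threshold_stats",
    "likelihood_ratios",
    "auc_brute_force",
    "delong_compare",
    "auc_variance",
    "detect_orientation",
]

POSITIVE = "higher_predicts_responder"
NEGATIVE = "lower_predicts_responder"


class DegenerateLabelsError(ValueError):
    """Both outcome classes are required but one is empty."""


class InsufficientPairingWarning(UserWarning):
    """Paired AUC comparison on very few patients."""


def _as_arrays(values, labels):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-d arrays of equal length")
    if not np.isfinite(v).all():
        raise ValueError("marker values must be finite")
    if y.all() or not y.any():
        raise DegenerateLabelsError("need at least one responder and one non-responder")
    return v, y


def _mann_whitney_auc(oriented: np.ndarray, y: np.ndarray) -> float:
    r = stats.rankdata(oriented)
    m = int(y.sum())
    n = y.size - m
    return float((r[y].sum() - m * (m + 1) / 2) / (m * n))


@dataclass
class RocCurve:
    """ROC points for one marker: aligned threshold / Se / Sp arrays."""

    marker: str
    orientation: str
    thresholds: np.ndarray  # strictly increasing, original scale
    se: np.ndarray
    sp: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def trapezoid_auc(self) -> float:
        """Area under the (1-Sp, Se) polyline, closed at (0,0) and (1,1).

        Equals the Mann-Whitney ``auc`` on every input; kept separate so
        the equivalence stays testable.
        """
        fpr = np.concatenate([[0.0], 1.0 - self.sp, [1.0]])
        tpr = np.concatenate([[0.0], self.se, [1.0]])
        # lexicographic sort keeps vertical segments traced bottom-up so
        # tied-FPR vertices connect at the correct height
        order = np.lexsort((tpr, fpr))
        return float(np.trapezoid(tpr[order], fpr[order]))

    def data_min(self) -> float:
        """Smallest observed marker value (excludes the sentinel)."""
        return float(self.thresholds[1] if self.orientation == POSITIVE else self.thresholds[0])

    def data_max(self) -> float:
        return float(self.thresholds[-1] if self.orientation == POSITIVE else self.thresholds[-2])


@dataclass
class ThresholdStats:
    """Operating characteristics of a single cut-off."""

    threshold: float
    se: float
    sp: float
    youden_j: float
    lr_pos: float
    lr_neg: float


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p: float
    n_paired: int


def empirical_roc(
    values,
    labels,
    orientation: str = POSITIVE,
    marker: str = "",
    candidates: str = "observed",
) -> RocCurve:
    """Build the empirical ROC curve over candidate thresholds.

    ``candidates="observed"`` (default) uses the unique observed values,
    reproducing the integer cut-offs clinicians quote for integer-valued
    markers; ``"midpoint"`` uses midpoints between consecutive unique
    values instead. Both include a sentinel one unit outside the range at
    which everyone is called positive. AUC is the normalized Mann-Whitney
    statistic (ties 1/2) and does not depend on the candidate rule.
    """
    v, y = _as_arrays(values, labels)
    if orientation not in (POSITIVE, NEGATIVE):
        raise ValueError(f"unknown orientation {orientation!r}")
    s = v if orientation == POSITIVE else -v
    uniq = np.unique(s)
    if candidates == "observed":
        cand = np.concatenate([[uniq[0] - 1.0], uniq])
    elif candidates == "midpoint":
        cand = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    else:
        raise ValueError(f"unknown candidate rule {candidates!r}")
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    tp = pos.size - np.searchsorted(pos, cand, side="left")
    fp = neg.size - np.searchsorted(neg, cand, side="left")
    se = tp / pos.size
    sp = 1.0 - fp / neg.size
    auc = _mann_whitney_auc(s, y)
    if orientation == NEGATIVE:
        cand, se, sp = -cand[::-1], se[::-1], sp[::-1]
    return RocCurve(
        marker=marker,
        orientation=orientation,
        thresholds=cand,
        se=se,
        sp=sp,
        auc=auc,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def likelihood_ratios(se: float, sp: float) -> tuple[float, float]:
    """LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp.

    Degenerate specificities yield flagged infinities (with a warning)
    rather than exceptions: LR+ at Sp=1, LR- at Sp=0.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if sp == 1.0:
        warnings.warn("LR+ undefined at Sp = 1; returning inf", UserWarning, stacklevel=2)
        lr_pos = np.inf
    else:
        lr_pos = se / (1.0 - sp)
    if sp == 0.0:
        if se == 1.0:
            lr_neg = np.nan
        else:
            warnings.warn("LR- undefined at Sp = 0; returning inf", UserWarning, stacklevel=2)
            lr_neg = np.inf
    else:
        lr_neg = (1.0 - se) / sp
    return float(lr_pos), float(lr_neg)


def threshold_stats(roc: RocCurve, index: int) -> ThresholdStats:
    se, sp = float(roc.se[index]), float(roc.sp[index])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        lr_pos, lr_neg = likelihood_ratios(se, sp)
    return ThresholdStats(
        threshold=float(roc.thresholds[index]),
        se=se,
        sp=sp,
        youden_j=se + sp - 1.0,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
    )


def youden_threshold(roc: RocCurve) -> ThresholdStats:
    """The candidate threshold maximizing J = Se + Sp - 1.

    Ties are broken toward the higher sensitivity (the screening-oriented
    rule: a positive-orientation marker returns the smallest tied
    threshold, a negative-orientation marker the largest).
    """
    j = roc.se + roc.sp - 1.0
    tied = np.flatnonzero(j >= j.max() - 1e-12)
    k = tied[np.argmax(roc.se[tied])]
    return threshold_stats(roc, int(k))


def detect_orientation(values, labels) -> str:
    """Orientation from group means: responders higher -> positive."""
    v, y = _as_arrays(values, labels)
    return POSITIVE if v[y].mean() >= v[~y].mean() else NEGATIVE


def auc_brute_force(values, labels, orientation: str = POSITIVE) -> float:
    """All-pairs AUC oracle: fraction of (pos, neg) pairs ordered correctly,
    ties counted 1/2. Quadratic; intended for small test instances."""
    v, y = _as_arrays(values, labels)
    s = v if orientation == POSITIVE else -v
    diff = np.subtract.outer(s[y], s[~y])
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / diff.size)


# ---------------------------------------------------------------------------
# DeLong

def _placements(oriented: np.ndarray, y: np.ndarray):
    """Placement values (structural components) for one marker.

    V10[i] = P-hat(X_i beats a random control), V01[j] likewise for
    controls; computed via midranks in O(n log n).
    """
    pos = oriented[y]
    neg = oriented[~y]
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - stats.rankdata(neg)) / m
    return float(v10.mean()), v10, v01


def auc_variance(values, labels, orientation: str = POSITIVE) -> tuple[float, float]:
    """DeLong variance of a single empirical AUC; returns (auc, var)."""
    v, y = _as_arrays(values, labels)
    s = v if orientation == POSITIVE else -v
    auc, v10, v01 = _placements(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return auc, float(var)


def delong_compare(
    values_a,
    values_b,
    labels,
    orientation_a: str = POSITIVE,
    orientation_b: str = POSITIVE,
) -> DeLongResult:
    """DeLong's test for the difference of two correlated AUCs.

    Both markers must be measured on the same patients (pairing by
    position). The variance of AUC_a - AUC_b is estimated from the
    covariance of placement values; the test statistic is referred to the
    standard normal, two-sided.
    """
    va, y = _as_arrays(values_a, labels)
    vb, y2 = _as_arrays(values_b, labels)
    if va.size != vb.size:
        raise ValueError("paired markers must have equal length")
    if va.size < 10:
        warnings.warn(
            f"only {va.size} paired observations; DeLong comparison is unreliable",
            InsufficientPairingWarning,
            stacklevel=2,
        )
    sa = va if orientation_a == POSITIVE else -va
    sb = vb if orientation_b == POSITIVE else -vb
    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var = max(float(var), 0.0)
    delta = auc_a - auc_b
    if var == 0.0:
        z = 0.0 if delta == 0.0 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if var == 0.0 and delta == 0.0:
        p = 1.0
    return DeLongResult(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=float(delta),
        variance=var,
        z=float(z),
        p=p,
        n_paired=int(va.size),
    )
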