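"""Risk/benefit threshold selection with asymmetric misclassification costs.

A false positive (fluid given to a non-responder) is weighted R times a
false negative (fluid withheld from a responder); R follows ARDS
severity: 2 below a PaO2/FiO2 of 100 (fluid overload is the dominant
risk), 1 below 200, and 0.5 at or above 200 (hypovolemia dominates). The
selected cut-off minimizes the total cost sum(R_i * FP_i) + sum(FN_i)
over candidate thresholds, which reduces exactly to Youden maximization
for uniform R = 1 with balanced classes. The cost-weighted grey zone is
reconstructed as the wider of the bootstrap CI of cost-optimal
thresholds and the unweighted tolerance zone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import grey_zone, roc_core
from .grey_zone import BootstrapConfig, GreyZone, bootstrap_thresholds, combine_grey_zone, tolerance_zone
from .roc_core import POSITIVE, ThresholdStats, empirical_roc

__all__ = ["CostSpec", "cost_optimal_threshold", "stratified_cost_analysis"]

#: Minimum complete cases for a per-stratum analysis.
MIN_STRATUM_N = 10


@dataclass
class CostSpec:
    """False-positive / false-negative cost ratio per ARDS stratum."""

    ratio_by_stratum: dict = field(
        default_factory=lambda: {"severe": 2.0, "moderate": 1.0, "mild": 0.5}
    )
    global_ratio: Optional[float] = None

    def ratio_for(self, stratum: str) -> float:
        if self.global_ratio is not None:
            return self.global_ratio
        return self.ratio_by_stratum[stratum]

    def __post_init__(self):
        ratios = list(self.ratio_by_stratum.values())
        if self.global_ratio is not None:
            ratios.append(self.global_ratio)
        if any(r <= 0 for r in ratios):
            raise ValueError("cost ratios must be positive")


def cost_optimal_threshold(
    values,
    labels,
    costs_fp,
    costs_fn,
    orientation: str = POSITIVE,
) -> ThresholdStats:
    """Threshold minimizing total per-patient misclassification cost.

    ``costs_fp`` / ``costs_fn`` may be scalars (uniform costs, e.g.
    ``costs_fp=R, costs_fn=1``) or per-patient arrays aligned with
    ``values``. Ties resolve as in Youden selection (toward sensitivity).
    """
    v = np.asarray(values, float)
    cfp = np.broadcast_to(np.asarray(costs_fp, float), v.shape)
    cfn = np.broadcast_to(np.asarray(costs_fn, float), v.shape)
    if (cfp <= 0).any() or (cfn <= 0).any():
        raise ValueError("costs must be positive")
    t = grey_zone.scan_optimal_threshold(
        values, labels, orientation=orientation, fn_cost=cfn, fp_cost=cfp
    )
    roc = empirical_roc(values, labels, orientation=orientation)
    idx = int(np.searchsorted(roc.thresholds, t))
    idx = min(idx, roc.thresholds.size - 1)
    if roc.thresholds[idx] != t:  # sentinel thresholds sit off the grid
        idx = int(np.argmin(np.abs(roc.thresholds - t)))
    return roc_core.threshold_stats(roc, idx)


def _sub_seed(seed: int, tag: str) -> int:
    return int((seed + zlib.crc32(tag.encode())) % (2**31))


def _marker_analysis(values, labels, ratio_fp, orientation, bconfig, tolerance):
    """AUC + bootstrap CI, cost-optimal threshold and reconstructed grey
    zone for one patient subset with per-patient FP cost weights."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    cfn = np.ones_like(values)
    cfp = np.broadcast_to(np.asarray(ratio_fp, float), values.shape)
    stats_at_best = cost_optimal_threshold(values, labels, cfp, cfn, orientation)
    boot = bootstrap_thresholds(
        values, labels, orientation=orientation, config=bconfig, fn_cost=cfn, fp_cost=cfp
    )
    roc = empirical_roc(values, labels, orientation=orientation)
    tz = tolerance_zone(roc, tolerance)
    zone = combine_grey_zone(boot.threshold_ci, tz, tolerance)
    if not zone.empty:
        zone.membership_fraction = grey_zone.membership(values, zone)
    auc, auc_var = roc_core.auc_variance(values, labels, orientation)
    return {
        "n": int(values.size),
        "n_responders": int(labels.sum()),
        "auc": auc,
        "auc_ci": boot.auc_ci,
        "auc_median_boot": boot.auc_median,
        "threshold": stats_at_best.threshold,
        "se": stats_at_best.se,
        "sp": stats_at_best.sp,
        "threshold_ci": boot.threshold_ci,
        "tolerance_zone": tz,
        "grey_zone": zone,
    }


def stratified_cost_analysis(
    cohort,
    marker: str = "ppv_pct",
    cost_spec: Optional[CostSpec] = None,
    bootstrap_config: Optional[BootstrapConfig] = None,
    orientation: str = POSITIVE,
    tolerance: float = 0.10,
) -> dict:
    """Cost-weighted threshold analysis per ARDS stratum and pooled.

    Patients need the marker, a responder label and a PaO2/FiO2 stratum;
    the pooled analysis weights each patient's false-positive cost by the
    R of their own stratum. Strata with fewer than 10 complete cases are
    reported as insufficient rather than analysed.
    """
    cost_spec = cost_spec or CostSpec()
    bconfig = bootstrap_config or BootstrapConfig()
    df = cohort.df if hasattr(cohort, "df") else cohort
    ok = df[marker].notna() & df["responder"].notna() & (df["ards_stratum"] != "unknown")
    sub = df[ok]
    out: dict = {"marker": marker, "strata": {}}
    for stratum in ("severe", "moderate", "mild"):
        rows = sub[sub["ards_stratum"] == stratum]
        labels = rows["responder"].astype(bool).to_numpy()
        if len(rows) < MIN_STRATUM_N or labels.all() or not labels.any():
            out["strata"][stratum] = {"status": "insufficient", "n": int(len(rows))}
            continue
        cfg = BootstrapConfig(bconfig.n_resamples, _sub_seed(bconfig.seed, stratum))
        res = _marker_analysis(
            rows[marker].to_numpy(), labels, cost_spec.ratio_for(stratum),
            orientation, cfg, tolerance,
        )
        res["status"] = "ok"
        res["cost_ratio"] = cost_spec.ratio_for(stratum)
        out["strata"][stratum] = res
    labels = sub["responder"].astype(bool).to_numpy()
    ratios = sub["ards_stratum"].map(cost_spec.ratio_for).to_numpy(float)
    if len(sub) >= MIN_STRATUM_N and labels.any() and not labels.all():
        cfg = BootstrapConfig(bconfig.n_resamples, _sub_seed(bconfig.seed, "pooled"))
        pooled = _marker_analysis(
            sub[marker].to_numpy(), labels, ratios, orientation, cfg, tolerance
        )
        pooled["status"] = "ok"
    else:
        pooled = {"status": "insufficient", "n": int(len(sub))}
    out["pooled"] = pooled
    return out
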