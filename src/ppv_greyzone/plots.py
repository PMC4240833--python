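"""Figure helpers (two-curve grey-zone plot, bootstrapped ROC)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .grey_zone import GreyZone
from .roc_core import RocCurve

__all__ = ["grey_zone_plot", "roc_plot"]


def grey_zone_plot(roc: RocCurve, zone: GreyZone, values=None, ax=None):
    """Sensitivity (blue), specificity (red) and, optionally, the percent
    of patients at or below each threshold (green), with the grey zone
    shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(roc.thresholds, 100 * roc.se, color="tab:blue", label="sensitivity")
    ax.plot(roc.thresholds, 100 * roc.sp, color="tab:red", label="specificity")
    if values is not None:
        v = np.sort(np.asarray(values, float))
        v = v[np.isfinite(v)]
        pct = 100 * np.arange(1, v.size + 1) / v.size
        ax.plot(v, pct, color="tab:green", label="% patients")
    if not zone.empty:
        ax.axvspan(zone.lower, zone.upper, color="0.8", alpha=0.6, label="grey zone")
    ax.axhline(90, color="0.5", lw=0.8, ls="--")
    ax.set_xlabel(f"{roc.marker or 'marker'} threshold")
    ax.set_ylabel("%")
    ax.set_ylim(0, 101)
    ax.legend(loc="center right", fontsize=8)
    return ax


def roc_plot(roc: RocCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - roc.sp, roc.se, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{roc.marker or 'marker'}  AUC = {roc.auc:.2f}")
    return ax
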