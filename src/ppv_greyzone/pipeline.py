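"""Full-cohort analysis pipeline.

Chains the stages of a grey-zone diagnostic-accuracy study: validity
filtering, responder/non-responder group comparison, per-marker ROC with
bootstrap, two-step grey zones, grey-zone membership comparison,
ventilator-variable subgroup analysis, the PPV/ΔSV correlation, and the
cost-ratio-weighted analysis. Computation is separated from rendering:
every stage returns plain dict/DataFrame results collected into a
:class:`ReportBundle`; serialization applies the reporting resolution
(integer % and mmHg for PPV/CVP thresholds) while internal values keep
full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__, roc_core
from .cohort_model import Cohort, apply_validity_filters, read_cohort
from .cost_weighted import CostSpec, stratified_cost_analysis
from .grey_zone import (
    BootstrapConfig,
    bootstrap_thresholds,
    combine_grey_zone,
    compare_membership,
    membership,
    tolerance_zone,
)
from .roc_core import NEGATIVE, POSITIVE, auc_variance, delong_compare, empirical_roc, youden_threshold

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "compare_groups",
    "marker_grey_zone_analysis",
    "subgroup_analysis",
    "ppv_co_correlation",
    "run_full_analysis",
]

DEFAULT_MARKERS = [("ppv_pct", POSITIVE), ("cvp_mmhg", NEGATIVE)]

#: Markers reported at integer resolution (native clinical units).
INTEGER_RESOLUTION = {"ppv_pct", "cvp_mmhg"}

#: Ventilator-variable strata: (label, column, predicate descriptions)
DEFAULT_SUBGROUPS = [
    ("vt_per_ibw", "vt_per_ibw", 8.0, "lt"),  # <8 vs >=8 ml/kg
    ("driving_pressure", "driving_pressure", 20.0, "le"),  # <=20 vs >20 cmH2O
    ("cst_rs", "cst_rs", 30.0, "le"),  # <=30 vs >30 ml/cmH2O
    ("hr_rr", "hr_rr", 3.6, "le"),  # <=3.6 vs >3.6
    ("vasopressor", "vasopressor", None, "bool"),
]


@dataclass
class AnalysisConfig:
    markers: list = field(default_factory=lambda: list(DEFAULT_MARKERS))
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    tolerance: float = 0.10
    subgroups: list = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    cost_spec: CostSpec = field(default_factory=CostSpec)
    min_stratum_n: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tolerance < 0.5:
            raise ValueError("tolerance must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kw = {}
        if "markers" in d:
            kw["markers"] = [tuple(m) for m in d["markers"]]
        if "bootstrap" in d:
            kw["bootstrap"] = BootstrapConfig(**d["bootstrap"])
        for key in ("tolerance", "seed", "min_stratum_n"):
            if key in d:
                kw[key] = d[key]
        if "cost_spec" in d:
            kw["cost_spec"] = CostSpec(**d["cost_spec"])
        if "subgroups" in d:
            kw["subgroups"] = [tuple(s) for s in d["subgroups"]]
        return cls(**kw)


@dataclass
class ReportBundle:
    group_comparison: pd.DataFrame
    markers: dict
    membership_comparison: Optional[dict]
    subgroups: pd.DataFrame
    cost_analysis: dict
    correlation: Optional[dict]
    metadata: dict


# ---------------------------------------------------------------------------
# group comparison

_CONTINUOUS = [
    "age",
    "height_cm",
    "weight_kg",
    "ibw_kg",
    "hr_bpm",
    "map_mmhg",
    "rr_cpm",
    "vt_per_ibw",
    "peep_cmh2o",
    "pplat_cmh2o",
    "driving_pressure",
    "cst_rs",
    "hr_rr",
    "pf_ratio",
    "cvp_mmhg",
    "sv_pre_ml",
    "ppv_pct",
]
_CATEGORICAL = ["sex", "vasopressor"]

#: Shapiro-Wilk group size cap; larger groups are screened on a
#: deterministic evenly spaced subsample.
_SHAPIRO_CAP = 500


def _normalish(x: np.ndarray) -> bool:
    if x.size < 3:
        return True
    if np.ptp(x) == 0:
        return False
    if x.size > _SHAPIRO_CAP:
        x = x[np.linspace(0, x.size - 1, _SHAPIRO_CAP).astype(int)]
    return stats.shapiro(x).pvalue >= 0.05


def compare_groups(cohort: Cohort, variables: Optional[list[str]] = None) -> pd.DataFrame:
    """Responder vs non-responder comparison table.

    Continuous variables: Welch t-test, falling back to Mann-Whitney when
    a Shapiro normality screen fails in either group. Categorical
    variables: chi-square, or Fisher's exact test when any expected cell
    count is below 5. Variables with fewer than 3 observations per group
    are flagged not-testable.
    """
    df = cohort.df[cohort.df["responder"].notna()]
    resp = df[df["responder"].astype(bool)]
    nonresp = df[~df["responder"].astype(bool)]
    variables = variables or [
        v for v in _CONTINUOUS + _CATEGORICAL if v in df.columns
    ]
    rows = []
    for var in variables:
        if var in _CATEGORICAL:
            tab = pd.crosstab(df[var], df["responder"].astype(bool))
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append({"variable": var, "test": "not-testable", "p": np.nan})
                continue
            expected = stats.contingency.expected_freq(tab.to_numpy())
            if (expected < 5).any():
                if tab.shape == (2, 2):
                    test, p = "fisher", stats.fisher_exact(tab.to_numpy())[1]
                else:
                    test, p = "chi2", stats.chi2_contingency(tab.to_numpy(), correction=False)[1]
            else:
                test, p = "chi2", stats.chi2_contingency(tab.to_numpy(), correction=False)[1]
            counts = tab.to_dict()
            rows.append(
                {
                    "variable": var,
                    "responder_n": int(tab[True].sum()),
                    "nonresponder_n": int(tab[False].sum()),
                    "test": test,
                    "p": float(p),
                    "levels": json.dumps({str(k): {str(i): int(c) for i, c in v.items()} for k, v in counts.items()}),
                }
            )
            continue
        a = resp[var].dropna().to_numpy(float)
        b = nonresp[var].dropna().to_numpy(float)
        row = {
            "variable": var,
            "responder_mean": a.mean() if a.size else np.nan,
            "responder_sd": a.std(ddof=1) if a.size > 1 else np.nan,
            "responder_n": int(a.size),
            "nonresponder_mean": b.mean() if b.size else np.nan,
            "nonresponder_sd": b.std(ddof=1) if b.size > 1 else np.nan,
            "nonresponder_n": int(b.size),
        }
        if a.size < 3 or b.size < 3:
            row.update(test="not-testable", p=np.nan)
        elif np.ptp(np.concatenate([a, b])) == 0:
            row.update(test="degenerate", p=1.0)
        elif _normalish(a) and _normalish(b):
            row.update(test="welch-t", p=float(stats.ttest_ind(a, b, equal_var=False).pvalue))
        else:
            row.update(
                test="mann-whitney",
                p=float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue),
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-marker grey zone

def marker_grey_zone_analysis(
    cohort: Cohort,
    marker: str,
    orientation: str,
    bootstrap: Optional[BootstrapConfig] = None,
    tolerance: float = 0.10,
) -> dict:
    """ROC, Youden threshold, bootstrap threshold CI, two-step grey zone
    and membership for one marker on its complete cases."""
    bootstrap = bootstrap or BootstrapConfig()
    sub = cohort.marker_complete(marker)
    values = sub[marker].to_numpy(float)
    labels = sub["responder"].astype(bool).to_numpy()
    roc = empirical_roc(values, labels, orientation=orientation, marker=marker)
    best = youden_threshold(roc)
    boot = bootstrap_thresholds(values, labels, orientation=orientation, config=bootstrap)
    tz = tolerance_zone(roc, tolerance)
    zone = combine_grey_zone(boot.threshold_ci, tz, tolerance)
    if not zone.empty:
        zone.membership_fraction = membership(values, zone)
    return {
        "marker": marker,
        "orientation": orientation,
        "n": int(values.size),
        "n_responders": int(labels.sum()),
        "roc": roc,
        "auc": roc.auc,
        "auc_median_boot": boot.auc_median,
        "auc_ci": boot.auc_ci,
        "best": best,
        "threshold_ci": boot.threshold_ci,
        "tolerance_zone": tz,
        "grey_zone": zone,
        "n_degenerate_redrawn": boot.n_degenerate_redrawn,
        "values": values,
        "labels": labels,
    }


# ---------------------------------------------------------------------------
# subgroups

def _split(df: pd.DataFrame, column: str, cut, mode: str):
    if mode == "bool":
        flag = df[column].fillna(False).astype(bool)
        return [(f"{column}=yes", df[flag]), (f"{column}=no", df[~flag])]
    have = df[df[column].notna()]
    if mode == "lt":
        return [
            (f"{column}<{cut}", have[have[column] < cut]),
            (f"{column}>={cut}", have[have[column] >= cut]),
        ]
    if mode == "le":
        return [
            (f"{column}<={cut}", have[have[column] <= cut]),
            (f"{column}>{cut}", have[have[column] > cut]),
        ]
    raise ValueError(f"unknown split mode {mode!r}")


def subgroup_analysis(
    cohort: Cohort,
    marker: str = "ppv_pct",
    orientation: str = POSITIVE,
    subgroups: Optional[list] = None,
    bootstrap: Optional[BootstrapConfig] = None,
    tolerance: float = 0.10,
    min_n: int = 20,
) -> pd.DataFrame:
    """Marker accuracy within ventilator-variable strata.

    For each stratifier the cohort's complete cases are split in two;
    each stratum gets n, AUC with bootstrap CI, the Youden threshold and
    the two-step grey zone. AUCs of the two (disjoint) strata are
    compared with an independent-samples normal z-test on the DeLong
    variances. Strata below ``min_n`` complete cases are skipped with a
    log row.
    """
    bootstrap = bootstrap or BootstrapConfig()
    subgroups = subgroups if subgroups is not None else DEFAULT_SUBGROUPS
    base = cohort.marker_complete(marker)
    rows = []
    for si, (label, column, cut, mode) in enumerate(subgroups):
        if column not in base.columns:
            rows.append({"stratifier": label, "stratum": "-", "status": "missing column"})
            continue
        parts = _split(base, column, cut, mode)
        part_stats = []
        for pi, (name, sub) in enumerate(parts):
            labels = sub["responder"].astype(bool).to_numpy()
            if len(sub) < min_n or labels.all() or not labels.any():
                rows.append(
                    {"stratifier": label, "stratum": name, "n": int(len(sub)), "status": "skipped"}
                )
                part_stats.append(None)
                continue
            values = sub[marker].to_numpy(float)
            cfg = BootstrapConfig(bootstrap.n_resamples, (bootstrap.seed + 1000 * si + pi) % 2**31)
            res = marker_grey_zone_analysis(
                Cohort(df=sub), marker, orientation, cfg, tolerance
            )
            auc, var = auc_variance(values, labels, orientation)
            part_stats.append((auc, var))
            zone = res["grey_zone"]
            rows.append(
                {
                    "stratifier": label,
                    "stratum": name,
                    "n": int(len(sub)),
                    "status": "ok",
                    "auc": res["auc"],
                    "auc_ci_lo": res["auc_ci"][0],
                    "auc_ci_hi": res["auc_ci"][1],
                    "threshold": res["best"].threshold,
                    "grey_lower": zone.lower,
                    "grey_upper": zone.upper,
                    "grey_source": zone.source,
                }
            )
        if len(part_stats) == 2 and all(s is not None for s in part_stats):
            (a1, v1), (a2, v2) = part_stats
            z = (a1 - a2) / np.sqrt(v1 + v2) if v1 + v2 > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z)))
            for row in rows[-2:]:
                row["p_auc_between"] = p
    return pd.DataFrame(rows)


def per_centre_grey_zones(
    cohort: Cohort,
    marker: str = "ppv_pct",
    orientation: str = POSITIVE,
    bootstrap: Optional[BootstrapConfig] = None,
    tolerance: float = 0.10,
    min_centre_n: int = 70,
) -> pd.DataFrame:
    """One grey zone per centre; centres below ``min_centre_n`` pooled as
    'others'."""
    bootstrap = bootstrap or BootstrapConfig()
    base = cohort.marker_complete(marker).copy()
    counts = base["centre"].value_counts()
    small = counts[counts < min_centre_n].index
    base["centre_group"] = base["centre"].where(~base["centre"].isin(small), "others")
    rows = []
    for gi, (name, sub) in enumerate(sorted(base.groupby("centre_group"), key=lambda kv: kv[0])):
        labels = sub["responder"].astype(bool).to_numpy()
        if labels.all() or not labels.any() or len(sub) < 20:
            rows.append({"centre": name, "n": int(len(sub)), "status": "skipped"})
            continue
        cfg = BootstrapConfig(bootstrap.n_resamples, (bootstrap.seed + 77 * gi) % 2**31)
        res = marker_grey_zone_analysis(Cohort(df=sub), marker, orientation, cfg, tolerance)
        zone = res["grey_zone"]
        rows.append(
            {
                "centre": name,
                "n": int(len(sub)),
                "status": "ok",
                "threshold": res["best"].threshold,
                "grey_lower": zone.lower,
                "grey_upper": zone.upper,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation

def ppv_co_correlation(cohort: Cohort, marker: str = "ppv_pct") -> Optional[dict]:
    """Pearson correlation of baseline PPV with the % stroke-volume change."""
    df = cohort.df[[marker, "delta_sv_pct"]].dropna()
    if len(df) < 3:
        return None
    r, p = stats.pearsonr(df[marker], df["delta_sv_pct"])
    return {"r": float(r), "p": float(p), "n": int(len(df))}


# ---------------------------------------------------------------------------
# orchestration + reporting

def _round_for_report(marker: str, x: float) -> float:
    if marker in INTEGER_RESOLUTION:
        return float(np.round(x))
    return float(np.round(x, 3))


def _marker_report(res: dict) -> dict:
    m = res["marker"]
    zone = res["grey_zone"]
    rep = {
        "marker": m,
        "orientation": res["orientation"],
        "n": res["n"],
        "n_responders": res["n_responders"],
        "auc": round(res["auc"], 3),
        "auc_median_boot": round(res["auc_median_boot"], 3),
        "auc_ci": [round(x, 3) for x in res["auc_ci"]],
        "best_threshold": _round_for_report(m, res["best"].threshold),
        "sensitivity": round(res["best"].se, 3),
        "specificity": round(res["best"].sp, 3),
        "youden_j": round(res["best"].youden_j, 3),
        "lr_pos": round(res["best"].lr_pos, 2) if np.isfinite(res["best"].lr_pos) else None,
        "lr_neg": round(res["best"].lr_neg, 2) if np.isfinite(res["best"].lr_neg) else None,
        "threshold_ci": [_round_for_report(m, x) for x in res["threshold_ci"]],
        "tolerance_zone": [_round_for_report(m, x) for x in res["tolerance_zone"]],
        "grey_zone": {
            "lower": _round_for_report(m, zone.lower),
            "upper": _round_for_report(m, zone.upper),
            "source": zone.source,
            "empty": zone.empty,
            "membership_pct": round(100 * zone.membership_fraction, 1)
            if zone.membership_fraction is not None
            else None,
        },
        "n_degenerate_redrawn": res["n_degenerate_redrawn"],
    }
    return rep


def run_full_analysis(
    cohort: Cohort | str | Path,
    config: Optional[AnalysisConfig | str | Path] = None,
    outdir: Optional[str | Path] = None,
) -> ReportBundle:
    """Execute the whole pipeline on a cohort (object or CSV path).

    Stages: validity filters -> group comparison -> per-marker ROC /
    bootstrap / grey zone -> membership comparison -> subgroups ->
    PPV-ΔSV correlation -> cost-weighted analysis. Deterministic under
    the configured seed; when ``outdir`` is given, tables go out as CSV
    and the summary as JSON.
    """
    if not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_yaml(config) if config is not None else AnalysisConfig()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    cohort = apply_validity_filters(cohort)

    groups = compare_groups(cohort)

    marker_results = {}
    marker_reports = {}
    for mi, (marker, orientation) in enumerate(config.markers):
        if marker not in cohort.df.columns or cohort.df[marker].notna().sum() == 0:
            marker_reports[marker] = {"marker": marker, "status": "absent"}
            continue
        cfg = BootstrapConfig(config.bootstrap.n_resamples, (config.bootstrap.seed + 31 * mi) % 2**31)
        res = marker_grey_zone_analysis(cohort, marker, orientation, cfg, config.tolerance)
        marker_results[marker] = res
        marker_reports[marker] = _marker_report(res)

    membership_cmp = None
    analysed = [m for m in marker_results.values() if not m["grey_zone"].empty]
    if len(analysed) >= 2:
        a, b = analysed[0], analysed[1]
        ka = int(round(a["grey_zone"].membership_fraction * a["n"]))
        kb = int(round(b["grey_zone"].membership_fraction * b["n"]))
        membership_cmp = {
            "marker_a": a["marker"],
            "marker_b": b["marker"],
            "fraction_a": a["grey_zone"].membership_fraction,
            "fraction_b": b["grey_zone"].membership_fraction,
            "p": compare_membership(ka, a["n"], kb, b["n"]),
        }
        # paired AUC comparison on the subset carrying both markers
        both = cohort.df[
            cohort.df[a["marker"]].notna()
            & cohort.df[b["marker"]].notna()
            & cohort.df["responder"].notna()
        ]
        if len(both) >= 10:
            dl = delong_compare(
                both[a["marker"]].to_numpy(float),
                both[b["marker"]].to_numpy(float),
                both["responder"].astype(bool).to_numpy(),
                orientation_a=a["orientation"],
                orientation_b=b["orientation"],
            )
            membership_cmp["delong"] = {
                "auc_a": round(dl.auc_a, 3),
                "auc_b": round(dl.auc_b, 3),
                "p": dl.p,
                "n_paired": dl.n_paired,
            }

    primary_marker, primary_orientation = config.markers[0]
    subgroups = subgroup_analysis(
        cohort,
        primary_marker,
        primary_orientation,
        config.subgroups,
        BootstrapConfig(config.bootstrap.n_resamples, (config.bootstrap.seed + 9001) % 2**31),
        config.tolerance,
        config.min_stratum_n,
    )

    cost = stratified_cost_analysis(
        cohort,
        primary_marker,
        config.cost_spec,
        BootstrapConfig(config.bootstrap.n_resamples, (config.bootstrap.seed + 4242) % 2**31),
        primary_orientation,
        config.tolerance,
    )

    corr = ppv_co_correlation(cohort, primary_marker)

    meta = {
        "software_version": __version__,
        "seed": config.bootstrap.seed,
        "n_analysed": cohort.n,
        "n_excluded": len(cohort.exclusion_log),
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "markers": config.markers,
                    "B": config.bootstrap.n_resamples,
                    "seed": config.bootstrap.seed,
                    "tolerance": config.tolerance,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }

    bundle = ReportBundle(
        group_comparison=groups,
        markers=marker_reports,
        membership_comparison=membership_cmp,
        subgroups=subgroups,
        cost_analysis=cost,
        correlation=corr,
        metadata=meta,
    )
    if outdir is not None:
        save_report(bundle, outdir)
    return bundle


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, bytes)):
        d = {k: v for k, v in vars(obj).items() if not isinstance(v, np.ndarray)}
        return _jsonify(d)
    return obj


def save_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write tables as CSV and the summary as deterministic JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.group_comparison.to_csv(outdir / "group_comparison.csv", index=False)
    bundle.subgroups.to_csv(outdir / "subgroups.csv", index=False)
    cost = {
        "marker": bundle.cost_analysis["marker"],
        "strata": {
            k: {kk: vv for kk, vv in v.items()}
            for k, v in bundle.cost_analysis["strata"].items()
        },
        "pooled": dict(bundle.cost_analysis["pooled"]),
    }
    summary = {
        "markers": bundle.markers,
        "membership_comparison": bundle.membership_comparison,
        "cost_analysis": cost,
        "correlation": bundle.correlation,
        "metadata": bundle.metadata,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
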