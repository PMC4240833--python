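"""Patient-level cohort model for fluid-responsiveness analyses.

A cohort is one row per patient: hemodynamic markers (pulse pressure
variation PPV, central venous pressure CVP, stroke volume before/after a
fluid challenge), ventilator variables, demographics and validity flags.
This module owns the derived-variable arithmetic (PPV from raw pulse
pressures, ideal body weight, driving pressure, respiratory-system
compliance, HR/RR, percent stroke-volume change), responder labelling
(ΔSV ≥ 15%), ARDS severity strata from the PaO2/FiO2 ratio, the validity
filter that mirrors the clinical exclusion rules, and delimited-text I/O.

Missing values propagate through every derivation rather than raising:
real pooled cohorts report a different available-n per variable, and the
analysis stages downstream each work on their own complete cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "DerivedVars",
    "Cohort",
    "InvalidInputError",
    "SchemaError",
    "ConsistencyWarning",
    "compute_ppv",
    "compute_ibw",
    "classify_responder",
    "assign_ards_stratum",
    "derive_all",
    "derive_frame",
    "build_cohort",
    "apply_validity_filters",
    "read_cohort",
    "write_cohort",
    "RESPONDER_THRESHOLD_PCT",
]

#: ΔSV (%) at or above which a patient is a fluid responder.
RESPONDER_THRESHOLD_PCT = 15.0

#: Consistency tolerance (percentage points) between a supplied PPV column
#: and PPV recomputed from raw pulse pressures.
PPV_CONSISTENCY_TOL = 0.5


class InvalidInputError(ValueError):
    """A physiologically impossible or ill-defined input."""


class SchemaError(ValueError):
    """Cohort file columns do not match the documented schema."""


class ConsistencyWarning(UserWarning):
    """Supplied and recomputed values disagree beyond tolerance."""


# ---------------------------------------------------------------------------
# scalar derivations

def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_ppv(pp_max: float, pp_min: float) -> float:
    """Pulse pressure variation (%) from max/min pulse pressure over the
    respiratory cycle: 100 * 2 * (PPmax - PPmin) / (PPmax + PPmin).

    Bounded in [0, 200]; raises :class:`InvalidInputError` when
    ``pp_max < pp_min`` or both pressures are zero.
    """
    if pp_max < pp_min:
        raise InvalidInputError(f"pp_max ({pp_max}) < pp_min ({pp_min})")
    if pp_min < 0:
        raise InvalidInputError("negative pulse pressure")
    if pp_max + pp_min == 0:
        raise InvalidInputError("both pulse pressures are zero")
    return 100.0 * 2.0 * (pp_max - pp_min) / (pp_max + pp_min)


def compute_ibw(sex: str, height_cm: float) -> float:
    """Ideal body weight (kg): 50 (men) or 45.5 (women) + 0.91*(height - 152.4)."""
    if height_cm <= 0:
        raise InvalidInputError(f"non-positive height {height_cm}")
    base = {"M": 50.0, "F": 45.5}.get(sex)
    if base is None:
        raise InvalidInputError(f"unknown sex code {sex!r} (expected 'M' or 'F')")
    return base + 0.91 * (height_cm - 152.4)


#: Relative slack keeping the inclusive 15% boundary robust to float
#: round-off (e.g. sv_post = 1.15 * sv_pre must classify as responder).
_BOUNDARY_EPS = 1e-9


def classify_responder(sv_pre: float, sv_post: float) -> bool:
    """True iff stroke volume rose by >= 15% after the fluid challenge."""
    if sv_pre <= 0:
        raise InvalidInputError(f"non-positive baseline stroke volume {sv_pre}")
    return 100.0 * (sv_post - sv_pre) / sv_pre >= RESPONDER_THRESHOLD_PCT - _BOUNDARY_EPS


def assign_ards_stratum(pf_ratio: Optional[float]) -> str:
    """ARDS severity from PaO2/FiO2: <100 severe, <200 moderate, >=200 mild.

    Missing ratio maps to ``"unknown"``.
    """
    if pf_ratio is None or (isinstance(pf_ratio, float) and math.isnan(pf_ratio)):
        return "unknown"
    if pf_ratio <= 0:
        raise InvalidInputError(f"non-positive PaO2/FiO2 ratio {pf_ratio}")
    if pf_ratio < 100:
        return "severe"
    if pf_ratio < 200:
        return "moderate"
    return "mild"


# ---------------------------------------------------------------------------
# records

@dataclass
class PatientRecord:
    """One patient's raw measurements; any field but id/sex/height may be missing."""

    patient_id: str
    centre: str = "unknown"
    age: Optional[float] = None
    sex: str = "M"
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    ppv: Optional[float] = None  # %
    pp_max: Optional[float] = None  # mmHg
    pp_min: Optional[float] = None  # mmHg
    cvp: Optional[float] = None  # mmHg
    sv_pre: Optional[float] = None  # ml
    sv_post: Optional[float] = None  # ml
    hr: Optional[float] = None  # beats/min
    map: Optional[float] = None  # mmHg
    rr: Optional[float] = None  # cycles/min
    vt: Optional[float] = None  # ml
    peep: Optional[float] = None  # cmH2O
    pplat: Optional[float] = None  # cmH2O
    pf_ratio: Optional[float] = None  # mmHg
    vasopressor: bool = False
    arrhythmia: bool = False
    spontaneous_breathing: bool = False
    suspected_iap: bool = False
    poor_echogenicity: bool = False


@dataclass
class DerivedVars:
    """Derived quantities for one patient; None where inputs were missing."""

    ibw: Optional[float] = None  # kg
    vt_per_ibw: Optional[float] = None  # ml/kg
    driving_pressure: Optional[float] = None  # cmH2O
    cst_rs: Optional[float] = None  # ml/cmH2O
    hr_rr: Optional[float] = None
    delta_sv_pct: Optional[float] = None  # %
    responder: Optional[bool] = None
    ards_stratum: str = "unknown"


def derive_all(record: PatientRecord) -> DerivedVars:
    """Compute every derivable quantity for one record.

    Missing inputs yield missing outputs (never an error); the only hard
    failure is the physically impossible ``pplat < peep``.
    """
    d = DerivedVars()
    if not _missing(record.height):
        d.ibw = compute_ibw(record.sex, record.height)
    if not _missing(record.vt) and d.ibw is not None:
        d.vt_per_ibw = record.vt / d.ibw
    if not _missing(record.pplat) and not _missing(record.peep):
        if record.pplat < record.peep:
            raise InvalidInputError(
                f"plateau pressure {record.pplat} below PEEP {record.peep} "
                f"for patient {record.patient_id}"
            )
        d.driving_pressure = record.pplat - record.peep
        if d.driving_pressure > 0 and not _missing(record.vt):
            d.cst_rs = record.vt / d.driving_pressure
    if not _missing(record.hr) and not _missing(record.rr) and record.rr > 0:
        d.hr_rr = record.hr / record.rr
    if not _missing(record.sv_pre) and not _missing(record.sv_post):
        d.delta_sv_pct = 100.0 * (record.sv_post - record.sv_pre) / record.sv_pre
        d.responder = classify_responder(record.sv_pre, record.sv_post)
    d.ards_stratum = assign_ards_stratum(record.pf_ratio)
    return d


# ---------------------------------------------------------------------------
# cohort frame

#: CSV schema: column -> (dtype kind, required)
SCHEMA = {
    "patient_id": ("str", True),
    "centre": ("str", False),
    "age": ("float", False),
    "sex": ("str", True),
    "height_cm": ("float", True),
    "weight_kg": ("float", False),
    "ppv_pct": ("float", False),
    "pp_max_mmhg": ("float", False),
    "pp_min_mmhg": ("float", False),
    "cvp_mmhg": ("float", False),
    "sv_pre_ml": ("float", False),
    "sv_post_ml": ("float", False),
    "hr_bpm": ("float", False),
    "map_mmhg": ("float", False),
    "rr_cpm": ("float", False),
    "vt_ml": ("float", False),
    "peep_cmh2o": ("float", False),
    "pplat_cmh2o": ("float", False),
    "pf_ratio": ("float", False),
    "ppv_method": ("str", False),
    "vasopressor": ("bool", False),
    "arrhythmia": ("bool", False),
    "spontaneous_breathing": ("bool", False),
    "suspected_iap": ("bool", False),
    "poor_echogenicity": ("bool", False),
}

RAW_COLUMNS = list(SCHEMA)
FLAG_COLUMNS = ["arrhythmia", "spontaneous_breathing", "suspected_iap", "poor_echogenicity"]
DERIVED_COLUMNS = [
    "ibw_kg",
    "vt_per_ibw",
    "driving_pressure",
    "cst_rs",
    "hr_rr",
    "delta_sv_pct",
    "responder",
    "ards_stratum",
]


@dataclass
class Cohort:
    """An ordered cohort frame plus the log of excluded patients."""

    df: pd.DataFrame
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.df)

    def responders(self) -> pd.DataFrame:
        return self.df[self.df["responder"] == True]  # noqa: E712 (nullable bool)

    def marker_complete(self, marker: str) -> pd.DataFrame:
        """Rows with the marker and a defined responder label."""
        ok = self.df[marker].notna() & self.df["responder"].notna()
        return self.df[ok]


def _reconcile_ppv(df: pd.DataFrame) -> pd.DataFrame:
    """Fill ppv_pct from raw pulse pressures where absent; warn on conflict.

    A supplied ppv_pct column wins over the recomputed value (source
    devices report PPV directly), but disagreement beyond 0.5 percentage
    points triggers a :class:`ConsistencyWarning`.
    """
    if "pp_max_mmhg" not in df or "pp_min_mmhg" not in df:
        return df
    raw_ok = df["pp_max_mmhg"].notna() & df["pp_min_mmhg"].notna()
    if not raw_ok.any():
        return df
    bad = raw_ok & (df["pp_max_mmhg"] < df["pp_min_mmhg"])
    if bad.any():
        raise InvalidInputError(
            f"pp_max < pp_min for patients {df.loc[bad, 'patient_id'].tolist()}"
        )
    s = df["pp_max_mmhg"] + df["pp_min_mmhg"]
    recomputed = 200.0 * (df["pp_max_mmhg"] - df["pp_min_mmhg"]) / s.where(s > 0)
    both = raw_ok & df["ppv_pct"].notna() & recomputed.notna()
    conflict = both & ((df["ppv_pct"] - recomputed).abs() > PPV_CONSISTENCY_TOL)
    if conflict.any():
        warnings.warn(
            f"supplied ppv_pct disagrees with raw pulse pressures by more than "
            f"{PPV_CONSISTENCY_TOL} points for "
            f"{df.loc[conflict, 'patient_id'].tolist()}; keeping supplied values",
            ConsistencyWarning,
            stacklevel=3,
        )
    df = df.copy()
    df["ppv_pct"] = df["ppv_pct"].where(df["ppv_pct"].notna(), recomputed)
    return df


def derive_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised counterpart of :func:`derive_all` over a cohort frame.

    Recomputes IBW from sex and height unconditionally (any supplied ibw
    column is ignored for uniformity across source centres).
    """
    df = _reconcile_ppv(df)
    out = df.copy()
    sexes = set(out["sex"].dropna().unique()) - {"M", "F"}
    if sexes:
        raise InvalidInputError(f"unknown sex codes {sorted(sexes)}")
    base = out["sex"].map({"M": 50.0, "F": 45.5})
    out["ibw_kg"] = base + 0.91 * (out["height_cm"] - 152.4)
    out["vt_per_ibw"] = out["vt_ml"] / out["ibw_kg"]
    both = out["pplat_cmh2o"].notna() & out["peep_cmh2o"].notna()
    bad = both & (out["pplat_cmh2o"] < out["peep_cmh2o"])
    if bad.any():
        raise InvalidInputError(
            f"plateau pressure below PEEP for {out.loc[bad, 'patient_id'].tolist()}"
        )
    dp = out["pplat_cmh2o"] - out["peep_cmh2o"]
    out["driving_pressure"] = dp
    out["cst_rs"] = out["vt_ml"] / dp.where(dp > 0)
    out["hr_rr"] = out["hr_bpm"] / out["rr_cpm"].where(out["rr_cpm"] > 0)
    out["delta_sv_pct"] = 100.0 * (out["sv_post_ml"] - out["sv_pre_ml"]) / out["sv_pre_ml"]
    resp = out["delta_sv_pct"] >= RESPONDER_THRESHOLD_PCT - _BOUNDARY_EPS
    out["responder"] = resp.astype("boolean").where(out["delta_sv_pct"].notna())
    out["ards_stratum"] = pd.cut(
        out["pf_ratio"],
        bins=[0, 100, 200, np.inf],
        labels=["severe", "moderate", "mild"],
        right=False,
    ).astype(object)
    out.loc[out["pf_ratio"].isna(), "ards_stratum"] = "unknown"
    return out


def build_cohort(df: pd.DataFrame) -> Cohort:
    """Derive all computed columns and wrap the frame as a :class:`Cohort`."""
    return Cohort(df=derive_frame(df).reset_index(drop=True))


EXCLUSION_REASONS = [
    ("arrhythmia", "arrhythmia"),
    ("spontaneous_breathing", "spontaneous breathing"),
    ("suspected_iap", "suspected intra-abdominal hypertension"),
    ("poor_echogenicity", "poor echogenicity"),
]


def apply_validity_filters(cohort: Cohort) -> Cohort:
    """Drop records in which PPV is not interpretable or the outcome is unknown.

    Mirrors the clinical exclusion flow: flagged conditions (arrhythmia,
    spontaneous breathing, suspected intra-abdominal hypertension, poor
    echogenicity), missing PPV, and missing responsiveness assessment.
    Each excluded patient is logged once with the first matching reason;
    the operation is idempotent.
    """
    df = cohort.df
    reason = pd.Series([None] * len(df), index=df.index, dtype=object)
    for col, label in EXCLUSION_REASONS:
        if col in df:
            flagged = df[col].fillna(False).astype(bool) & reason.isna()
            reason[flagged] = label
    reason[df["ppv_pct"].isna() & reason.isna()] = "no ppv measurement"
    reason[df["responder"].isna() & reason.isna()] = "no responsiveness assessment"
    excluded = reason.notna()
    log = list(cohort.exclusion_log) + list(
        zip(df.loc[excluded, "patient_id"], reason[excluded])
    )
    return Cohort(df=df[~excluded].reset_index(drop=True), exclusion_log=log)


# ---------------------------------------------------------------------------
# I/O

def _check_schema(columns: Iterable[str]) -> None:
    cols = set(columns)
    missing = [c for c, (_, req) in SCHEMA.items() if req and c not in cols]
    unknown = sorted(cols - set(SCHEMA))
    if missing or unknown:
        raise SchemaError(
            f"cohort file schema mismatch: missing required columns {missing}, "
            f"unknown columns {unknown}"
        )


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, validate the schema, and derive computed columns.

    Empty cells encode missing values; boolean columns accept 0/1 or
    true/false spellings.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "centre": str, "sex": str})
    _check_schema(df.columns)
    for col, (kind, _) in SCHEMA.items():
        if col not in df:
            if kind == "bool":
                df[col] = False
            elif col == "centre":
                df[col] = "unknown"
            else:
                df[col] = np.nan
        elif kind == "bool":
            df[col] = (
                df[col]
                .replace({"True": 1, "False": 0, "true": 1, "false": 0})
                .fillna(0)
                .astype(int)
                .astype(bool)
            )
        elif kind == "float":
            df[col] = pd.to_numeric(df[col], errors="raise")
    return build_cohort(df[RAW_COLUMNS])


def write_cohort(cohort: Cohort, path) -> None:
    """Write the raw measurement columns back to CSV (round-trip stable).

    Derived columns are omitted: they are recomputed on read, so a
    write-read cycle reproduces the cohort exactly.
    """
    out = cohort.df[[c for c in RAW_COLUMNS if c in cohort.df]].copy()
    for col, (kind, _) in SCHEMA.items():
        if kind == "bool" and col in out:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
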