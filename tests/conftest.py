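import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ppv_greyzone.cohort_model import build_cohort
from ppv_greyzone.synthetic_cohort import default_config, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_raw_frame(rows: list[dict]) -> pd.DataFrame:
    """Minimal raw cohort frame from per-patient dicts (schema defaults filled)."""
    base = {
        "patient_id": None,
        "centre": "A",
        "age": 60.0,
        "sex": "M",
        "height_cm": 170.0,
        "weight_kg": 75.0,
        "ppv_pct": 10.0,
        "pp_max_mmhg": np.nan,
        "pp_min_mmhg": np.nan,
        "cvp_mmhg": 10.0,
        "sv_pre_ml": 60.0,
        "sv_post_ml": 70.0,
        "hr_bpm": 90.0,
        "map_mmhg": 75.0,
        "rr_cpm": 18.0,
        "vt_ml": 420.0,
        "peep_cmh2o": 6.0,
        "pplat_cmh2o": 20.0,
        "pf_ratio": 180.0,
        "ppv_method": "auto",
        "vasopressor": False,
        "arrhythmia": False,
        "spontaneous_breathing": False,
        "suspected_iap": False,
        "poor_echogenicity": False,
    }
    out = []
    for i, row in enumerate(rows):
        d = dict(base)
        d["patient_id"] = f"p{i:03d}"
        d.update(row)
        out.append(d)
    return pd.DataFrame(out)


@pytest.fixture
def small_cohort():
    """Six hand-written patients: 3 responders, 3 non-responders."""
    rows = [
        {"ppv_pct": 18, "sv_pre_ml": 60, "sv_post_ml": 75},
        {"ppv_pct": 14, "sv_pre_ml": 50, "sv_post_ml": 60},
        {"ppv_pct": 11, "sv_pre_ml": 70, "sv_post_ml": 82},
        {"ppv_pct": 9, "sv_pre_ml": 60, "sv_post_ml": 62},
        {"ppv_pct": 6, "sv_pre_ml": 80, "sv_post_ml": 82},
        {"ppv_pct": 4, "sv_pre_ml": 66, "sv_post_ml": 60},
    ]
    return build_cohort(make_raw_frame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study conditions (n = 556)."""
    cfg = default_config()
    cfg.seed = 7
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort (n = 10^4) for moment-fidelity checks."""
    cfg = default_config()
    cfg.n = 10_000
    cfg.seed = 11
    return generate_cohort(cfg)
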