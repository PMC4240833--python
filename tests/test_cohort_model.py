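"""Cohort data model: derived arithmetic, labelling, filters and I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppv_greyzone import cohort_model as cm
from conftest import make_raw_frame


class TestComputePPV:
    @pytest.mark.parametrize(
        "pp_max, pp_min, expected",
        [(50, 50, 0.0), (60, 40, 40.0), (30, 0, 200.0)],
    )
    def test_formula(self, pp_max, pp_min, expected):
        assert cm.compute_ppv(pp_max, pp_min) == pytest.approx(expected)

    @pytest.mark.parametrize("pp_max, pp_min", [(40, 60), (0, 0), (10, -1)])
    def test_invalid_inputs(self, pp_max, pp_min):
        with pytest.raises(cm.InvalidInputError):
            cm.compute_ppv(pp_max, pp_min)

    @given(
        a=st.floats(1, 300),
        b=st.floats(0, 300),
        k=st.floats(0.01, 100),
    )
    def test_scale_invariant(self, a, b, k):
        hi, lo = max(a, b), min(a, b)
        assert cm.compute_ppv(k * hi, k * lo) == pytest.approx(
            cm.compute_ppv(hi, lo), rel=1e-9
        )


class TestComputeIBW:
    @pytest.mark.parametrize(
        "sex, height, expected",
        [("M", 152.4, 50.0), ("F", 152.4, 45.5), ("M", 172.4, 68.2)],
    )
    def test_formula(self, sex, height, expected):
        assert cm.compute_ibw(sex, height) == pytest.approx(expected)

    def test_unknown_sex(self):
        with pytest.raises(cm.InvalidInputError):
            cm.compute_ibw("X", 170)


class TestClassifyResponder:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [(60, 69, True), (60, 68.9, False), (74, 80, False)],
    )
    def test_threshold(self, pre, post, expected):
        assert cm.classify_responder(pre, post) is expected

    @given(s=st.floats(1, 500))
    def test_boundary_inclusive(self, s):
        assert cm.classify_responder(s, s * 1.15)

    def test_nonpositive_baseline(self):
        with pytest.raises(cm.InvalidInputError):
            cm.classify_responder(0, 10)


@pytest.mark.parametrize(
    "pf, expected",
    [(99, "severe"), (150, "moderate"), (100, "moderate"), (200, "mild"), (None, "unknown"), (np.nan, "unknown")],
)
def test_ards_stratum(pf, expected):
    assert cm.assign_ards_stratum(pf) == expected


class TestDeriveAll:
    def test_arithmetic(self):
        rec = cm.PatientRecord(
            patient_id="p", sex="M", height=163.4, vt=420, pplat=20, peep=6,
            hr=90, rr=18, sv_pre=60, sv_post=75,
        )
        d = cm.derive_all(rec)
        assert d.ibw == pytest.approx(60.01, abs=0.01)
        assert d.vt_per_ibw == pytest.approx(420 / d.ibw)
        assert d.driving_pressure == 14
        assert d.cst_rs == pytest.approx(30.0)
        assert d.hr_rr == pytest.approx(5.0)
        assert d.delta_sv_pct == pytest.approx(25.0)
        assert d.responder is True

    def test_missing_propagates(self):
        rec = cm.PatientRecord(patient_id="p", height=170, vt=420)
        d = cm.derive_all(rec)
        assert d.driving_pressure is None and d.cst_rs is None
        assert d.responder is None and d.delta_sv_pct is None

    def test_pplat_below_peep_rejected(self):
        rec = cm.PatientRecord(patient_id="p", height=170, pplat=5, peep=10)
        with pytest.raises(cm.InvalidInputError):
            cm.derive_all(rec)

    @given(
        vt=st.floats(100, 900),
        peep=st.floats(0, 15),
        dp=st.floats(1, 30),
    )
    def test_compliance_times_driving_pressure_is_vt(self, vt, peep, dp):
        rec = cm.PatientRecord(patient_id="p", height=170, vt=vt, peep=peep, pplat=peep + dp)
        d = cm.derive_all(rec)
        assert d.cst_rs * d.driving_pressure == pytest.approx(vt, rel=1e-12)


class TestValidityFilters:
    def test_exclusions_logged_with_reason(self):
        cohort = cm.build_cohort(
            make_raw_frame(
                [
                    {"arrhythmia": True},
                    {"sv_post_ml": np.nan},
                    {"ppv_pct": np.nan},
                    {},
                ]
            )
        )
        out = cm.apply_validity_filters(cohort)
        assert out.n == 1
        reasons = dict(out.exclusion_log)
        assert reasons["p000"] == "arrhythmia"
        assert reasons["p001"] == "no responsiveness assessment"
        assert reasons["p002"] == "no ppv measurement"

    def test_idempotent(self, default_cohort):
        once = cm.apply_validity_filters(default_cohort)
        twice = cm.apply_validity_filters(once)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert once.exclusion_log == twice.exclusion_log


class TestIO:
    def test_round_trip(self, tmp_path, default_cohort):
        path = tmp_path / "cohort.csv"
        cm.write_cohort(default_cohort, path)
        back = cm.read_cohort(path)
        pd.testing.assert_frame_equal(
            back.df, default_cohort.df.reset_index(drop=True), check_dtype=False
        )

    def test_blank_cell_is_missing(self, tmp_path):
        df = make_raw_frame([{}, {"cvp_mmhg": np.nan}, {}])
        path = tmp_path / "c.csv"
        cm.write_cohort(cm.build_cohort(df), path)
        back = cm.read_cohort(path)
        assert back.n == 3
        assert back.df["cvp_mmhg"].isna().tolist() == [False, True, False]

    def test_schema_mismatch_lists_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"patient_id": ["a"], "bogus": [1]}).to_csv(path, index=False)
        with pytest.raises(cm.SchemaError, match="bogus"):
            cm.read_cohort(path)

    def test_ppv_filled_from_raw_pulse_pressures(self):
        df = make_raw_frame([{"ppv_pct": np.nan, "pp_max_mmhg": 60.0, "pp_min_mmhg": 40.0}])
        out = cm.derive_frame(df)
        assert out["ppv_pct"].iloc[0] == pytest.approx(40.0)

    def test_conflicting_ppv_warns_and_keeps_supplied(self):
        df = make_raw_frame([{"ppv_pct": 10.0, "pp_max_mmhg": 60.0, "pp_min_mmhg": 40.0}])
        with pytest.warns(cm.ConsistencyWarning):
            out = cm.derive_frame(df)
        assert out["ppv_pct"].iloc[0] == 10.0
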