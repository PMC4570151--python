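"""SIRS detection, APS scoring, Elixhauser mapping, SOFA, KDIGO staging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sirsfluids as sf
from sirsfluids.phenotype import band_points, compute_aps, kdigo_stage, \
    sofa_components
from sirsfluids.tables import empty_table

D1, D2 = "2012-03-01 10:00", "2012-03-02 10:00"


class TestDetectSIRS:
    def test_tachycardia_plus_fever_same_day_qualifies(self, mk_vitals):
        vitals = mk_vitals([("E1", "heart_rate", 95, D1),
                            ("E1", "temperature", 38.5, D1)])
        ev = sf.detect_sirs(vitals, empty_table("labs"), encounter_id="E1")
        assert ev is not None
        assert ev.criteria_met == {"tachycardia", "temperature"}
        assert ev.qualification_date == pd.Timestamp("2012-03-01")

    def test_tachycardia_alone_never_qualifies(self, mk_vitals):
        vitals = mk_vitals([("E1", "heart_rate", 95, D1),
                            ("E1", "heart_rate", 97, D2)])
        assert sf.detect_sirs(vitals, empty_table("labs"), "E1") is None

    def test_wbc_bound_is_inclusive(self, mk_vitals, mk_labs):
        vitals = mk_vitals([("E1", "heart_rate", 91, D1)])
        labs = mk_labs([("E1", "wbc", 12.0, "serum", D1)])
        ev = sf.detect_sirs(vitals, labs, "E1")
        assert ev is not None and "leukocyte" in ev.criteria_met

    def test_heart_rate_bound_is_strict(self, mk_vitals):
        vitals = mk_vitals([("E1", "heart_rate", 90, D1),
                            ("E1", "temperature", 39.0, D1)])
        assert sf.detect_sirs(vitals, empty_table("labs"), "E1") is None

    def test_criteria_must_share_a_calendar_day(self, mk_vitals):
        vitals = mk_vitals([("E1", "heart_rate", 95, D1),
                            ("E1", "temperature", 38.5, D2)])
        assert sf.detect_sirs(vitals, empty_table("labs"), "E1") is None

    def test_earliest_qualifying_day_is_reported(self, mk_vitals):
        vitals = mk_vitals([("E1", "heart_rate", 95, D2),
                            ("E1", "temperature", 38.5, D2),
                            ("E1", "heart_rate", 95, "2012-03-05 10:00"),
                            ("E1", "temperature", 38.5, "2012-03-05 10:00")])
        ev = sf.detect_sirs(vitals, empty_table("labs"), "E1")
        assert ev.qualification_date == pd.Timestamp("2012-03-02")

    def test_low_temperature_and_paco2_arms_fire(self, mk_vitals, mk_labs):
        vitals = mk_vitals([("E1", "heart_rate", 95, D1),
                            ("E1", "temperature", 35.5, D1)])
        ev = sf.detect_sirs(vitals, empty_table("labs"), "E1")
        assert "temperature" in ev.criteria_met
        labs = mk_labs([("E2", "paco2", 30.0, "arterial", D1)])
        vitals = mk_vitals([("E2", "heart_rate", 95, D1)])
        ev = sf.detect_sirs(vitals, labs, "E2")
        assert "respiratory" in ev.criteria_met

    def test_adding_criterion_records_is_monotone(self, mk_vitals):
        """Extra abnormal readings can only keep or advance qualification."""
        base = mk_vitals([("E1", "heart_rate", 95, D2),
                          ("E1", "respiratory_rate", 22, D2)])
        ev0 = sf.detect_sirs(base, empty_table("labs"), "E1")
        extra = mk_vitals([("E1", "heart_rate", 101, D1),
                           ("E1", "temperature", 38.9, D1)])
        ev1 = sf.detect_sirs(pd.concat([base, extra]), empty_table("labs"), "E1")
        assert ev1 is not None
        assert ev1.qualification_date <= ev0.qualification_date


class TestAPS:
    def test_no_data_scores_zero(self, one_sirs):
        res = compute_aps(empty_table("labs"), empty_table("vitals"), one_sirs)
        assert res["aps"].tolist() == [0]

    def test_single_fever_scores_apache_temperature_band(self, one_sirs,
                                                         mk_vitals):
        vitals = mk_vitals([("E1", "temperature", 39.5, D2)])
        res = compute_aps(empty_table("labs"), vitals, one_sirs)
        assert res["aps"].tolist() == [3]  # 39.0-40.9 degC band

    def test_multivariable_day_total_matches_hand_scored_table(self, one_sirs,
                                                               mk_vitals,
                                                               mk_labs):
        # HR 142 -> 3, temp 38.7 -> 1, Na 154 -> 1, K 3.2 -> 1, creat 2.1 -> 3
        vitals = mk_vitals([("E1", "heart_rate", 142, D2),
                            ("E1", "temperature", 38.7, D2)])
        labs = mk_labs([("E1", "sodium", 154, "serum", D2),
                        ("E1", "potassium", 3.2, "serum", D2),
                        ("E1", "creatinine", 2.1, "serum", D2)])
        res = compute_aps(labs, vitals, one_sirs)
        assert res["aps"].tolist() == [9]

    def test_higher_of_day0_and_prior_day_totals_wins(self, one_sirs, mk_labs):
        labs = mk_labs([("E1", "creatinine", 1.0, "serum", D2),     # day 0: 0
                        ("E1", "creatinine", 3.6, "serum", D1)])    # day -1: 4
        res = compute_aps(labs, empty_table("vitals"), one_sirs)
        assert res["aps"].tolist() == [4]
        assert res["day_used"].tolist() == [-1]

    def test_oxygenation_uses_pao2_band_at_low_fio2(self, one_sirs, mk_labs):
        labs = mk_labs([("E1", "pao2", 60.0, "arterial", D2),
                        ("E1", "fio2", 0.40, "arterial", D2)])
        res = compute_aps(labs, empty_table("vitals"), one_sirs)
        assert res["aps"].tolist() == [3]  # PaO2 55-60 band

    def test_more_abnormal_value_never_lowers_score(self, one_sirs, mk_vitals):
        for hr, worse in [(120, 150), (80, 45), (100, 190)]:
            a = compute_aps(empty_table("labs"),
                            mk_vitals([("E1", "heart_rate", hr, D2)]), one_sirs)
            b = compute_aps(empty_table("labs"),
                            mk_vitals([("E1", "heart_rate", worse, D2)]),
                            one_sirs)
            assert b["aps"].iloc[0] >= a["aps"].iloc[0]

    def test_band_edges_match_apache_reference_points(self):
        # spot checks against the transcribed APACHE-II table
        assert band_points("heart_rate", [39, 40, 69, 70, 110, 180]).tolist() \
            == [4, 3, 2, 0, 2, 4]
        assert band_points("arterial_ph", [7.14, 7.2, 7.33, 7.49, 7.7]).tolist() \
            == [4, 3, 0, 0, 4]
        assert band_points("creatinine", [0.5, 0.6, 1.5, 2.0, 3.5]).tolist() \
            == [2, 0, 2, 3, 4]


class TestElixhauser:
    def mk_dx(self, codes):
        return pd.DataFrame({"encounter_id": ["E1"] * len(codes),
                             "icd9_code": codes,
                             "poa_flag": ["yes"] * len(codes),
                             "sequence": range(len(codes))})

    def test_renal_failure_unspecified_code_is_excluded(self, vocab):
        prof = sf.map_elixhauser(self.mk_dx(["586"]), vocab)
        cats = [c for c in prof.columns if c != "encounter_id"]
        assert not prof[cats].any(axis=None)

    def test_pvd_code_5579_is_excluded(self, vocab):
        prof = sf.map_elixhauser(self.mk_dx(["557.9"]), vocab)
        assert not prof["peripheral_vascular"].iloc[0]
        prof = sf.map_elixhauser(self.mk_dx(["557.1"]), vocab)
        assert prof["peripheral_vascular"].iloc[0]

    def test_chf_code_maps_to_congestive_heart_failure(self, vocab):
        for code in ["428.0", "4280", "39891"]:
            prof = sf.map_elixhauser(self.mk_dx([code]), vocab)
            assert prof["congestive_heart_failure"].iloc[0], code

    def test_fluid_electrolyte_category_absent(self, vocab):
        prof = sf.map_elixhauser(self.mk_dx(["2761"]), vocab)
        assert "fluid_electrolyte" not in prof.columns
        cats = [c for c in prof.columns if c != "encounter_id"]
        assert not prof[cats].any(axis=None)

    def test_unknown_codes_ignored(self, vocab):
        prof = sf.map_elixhauser(self.mk_dx(["V999", "0000"]), vocab)
        cats = [c for c in prof.columns if c != "encounter_id"]
        assert not prof[cats].any(axis=None)


class TestSOFA:
    def test_thrombocytopenia_scores_coagulation(self, one_sirs, mk_labs,
                                                 vocab):
        labs = mk_labs([("E1", "platelets", 120, "serum", D2)])
        res = sofa_components(labs, empty_table("med_orders"), one_sirs, vocab)
        assert res["coagulation"].iloc[0] == 1

    def test_no_data_scores_all_zero(self, one_sirs, vocab):
        res = sofa_components(empty_table("labs"), empty_table("med_orders"),
                              one_sirs, vocab)
        assert res[["cardio", "coagulation", "liver", "respiratory"]].to_numpy().sum() == 0

    def test_vasopressor_order_scores_cardio_three(self, one_sirs, mk_meds,
                                                   vocab):
        meds = mk_meds([("E1", "norepinephrine", "iv", D2)])
        res = sofa_components(empty_table("labs"), meds, one_sirs, vocab)
        assert res["cardio"].iloc[0] >= 3

    def test_bilirubin_band(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "bilirubin", 2.5, "serum", D2)])
        res = sofa_components(labs, empty_table("med_orders"), one_sirs, vocab)
        assert res["liver"].iloc[0] == 2

    def test_pf_ratio_band(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "pao2", 75.0, "arterial", D2),
                        ("E1", "fio2", 0.30, "arterial", D2)])  # ratio 250
        res = sofa_components(labs, empty_table("med_orders"), one_sirs, vocab)
        assert res["respiratory"].iloc[0] == 2


class TestKDIGO:
    def series(self, baseline_vals, window_vals):
        # baseline readings end on day -1 (qualification is 2012-03-02)
        nb = len(baseline_vals)
        base_days = [pd.Timestamp("2012-03-01") - pd.Timedelta(days=nb - 1 - i)
                     for i in range(nb)]
        rows = [("E1", "creatinine", v, "serum", d + pd.Timedelta(hours=8))
                for v, d in zip(baseline_vals, base_days)]
        rows += [("E1", "creatinine", v, "serum",
                  pd.Timestamp(f"2012-03-0{2+i} 08:00"))
                 for i, v in enumerate(window_vals)]
        return pd.DataFrame(
            [{"encounter_id": r[0], "analyte": r[1], "value": float(r[2]),
              "unit": "mg/dL", "specimen": r[3], "datetime": pd.Timestamp(r[4])}
             for r in rows])

    @pytest.mark.parametrize("baseline,window,stage", [
        ([1.0], [1.6], 1),        # >=1.5x
        ([1.0], [2.1], 2),        # >=2.0x
        ([1.0], [3.1], 3),        # >=3.0x
        ([1.0], [1.0, 1.1], 0),   # flat
        ([1.0], [1.4], 1),        # rise >=0.3 within 48 h
        ([2.8], [4.3], 3),        # peak >=4.0 with qualifying rise
        ([1.0], [1.2], 0),        # sub-threshold rise
    ])
    def test_creatinine_truth_table(self, one_sirs, baseline, window, stage):
        res = kdigo_stage(self.series(baseline, window), one_sirs)
        assert res["stage"].tolist() == [stage]

    def test_baseline_is_lowest_of_prior_week(self, one_sirs):
        res = kdigo_stage(self.series([1.4, 0.9, 1.2], [1.4]), one_sirs)
        assert res["baseline_creatinine"].iloc[0] == 0.9
        assert res["stage"].iloc[0] == 1  # 1.4/0.9 >= 1.5

    def test_missing_baseline_reports_not_aki(self, one_sirs):
        res = kdigo_stage(self.series([], [3.0]), one_sirs)
        assert res["stage"].tolist() == [0]
        assert np.isnan(res["baseline_creatinine"].iloc[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(peaks=st.lists(st.floats(0.5, 8.0), min_size=2, max_size=2))
    def test_stage_monotone_in_peak(self, peaks):
        sirs = pd.DataFrame([{"encounter_id": "E1",
                              "qualification_date": pd.Timestamp("2012-03-02"),
                              "tachycardia": True, "temperature": True,
                              "respiratory": False, "leukocyte": False}])
        lo, hi = sorted(peaks)
        s_lo = kdigo_stage(self.series([1.0], [lo]), sirs)["stage"].iloc[0]
        s_hi = kdigo_stage(self.series([1.0], [hi]), sirs)["stage"].iloc[0]
        assert s_hi >= s_lo


def test_all_scores_zero_on_empty_tables(one_sirs, vocab):
    aps = compute_aps(empty_table("labs"), empty_table("vitals"), one_sirs)
    sofa = sofa_components(empty_table("labs"), empty_table("med_orders"),
                           one_sirs, vocab)
    kd = kdigo_stage(empty_table("labs"), one_sirs)
    assert aps["aps"].tolist() == [0]
    assert sofa[["cardio", "coagulation", "liver", "respiratory"]].sum().sum() == 0
    assert kd["stage"].tolist() == [0]
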