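"""Administrative and clinical outcome adjudication and endpoints."""

import numpy as np
import pandas as pd
import pytest

import sirsfluids as sf
from sirsfluids.outcomes import (admin_outcomes, cardiac_clinical,
                                 hemorrhage_clinical, infection_clinical,
                                 gi_clinical, electrolyte_flags,
                                 acidosis_flags, encounter_endpoints)
from sirsfluids.tables import empty_table

D0, D1, D2 = "2012-03-02 10:00", "2012-03-03 10:00", "2012-03-04 10:00"


def dx(rows):
    return pd.DataFrame([{"encounter_id": r[0], "icd9_code": r[1],
                          "poa_flag": r[2], "sequence": 1.0} for r in rows])


class TestAdminOutcomes:
    def test_non_poa_code_counts(self, vocab):
        out = admin_outcomes(dx([("E1", "427.31", "no")]), vocab,
                             pd.Series(["E1"]))
        assert out["cardiac"].iloc[0]

    def test_present_on_admission_code_does_not_count(self, vocab):
        out = admin_outcomes(dx([("E1", "427.31", "yes")]), vocab,
                             pd.Series(["E1"]))
        assert not out["cardiac"].iloc[0]

    def test_unknown_poa_counts_as_outcome(self, vocab):
        out = admin_outcomes(dx([("E1", "584.9", "unknown")]), vocab,
                             pd.Series(["E1"]))
        assert out["acute_renal_failure"].iloc[0]

    def test_no_codes_all_false(self, vocab):
        out = admin_outcomes(empty_table("diagnoses"), vocab,
                             pd.Series(["E1"]))
        cats = [c for c in out.columns if c != "encounter_id"]
        assert not out[cats].any(axis=None)


class TestCardiacClinical:
    def test_iv_antiarrhythmic_in_window_is_dysrhythmia(self, one_sirs,
                                                        mk_meds, vocab):
        meds = mk_meds([("E1", "amiodarone", "iv", D2)])
        out = cardiac_clinical(meds, empty_table("labs"), one_sirs, vocab)
        assert out["dysrhythmia"].iloc[0]

    def test_oral_antiarrhythmic_does_not_count(self, one_sirs, mk_meds, vocab):
        meds = mk_meds([("E1", "amiodarone", "oral", D2)])
        out = cardiac_clinical(meds, empty_table("labs"), one_sirs, vocab)
        assert not out["dysrhythmia"].iloc[0]

    def test_bnp_above_600_with_same_day_diuretic_is_chf(self, one_sirs,
                                                         mk_meds, mk_labs,
                                                         vocab):
        labs = mk_labs([("E1", "bnp", 650, "serum", D1)])
        meds = mk_meds([("E1", "furosemide", "iv", D1)])
        out = cardiac_clinical(meds, labs, one_sirs, vocab)
        assert out["chf"].iloc[0]

    def test_bnp_without_diuretic_is_not_chf(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "bnp", 650, "serum", D1)])
        out = cardiac_clinical(empty_table("med_orders"), labs, one_sirs, vocab)
        assert not out["chf"].iloc[0]

    def test_diuretic_on_different_day_is_not_chf(self, one_sirs, mk_meds,
                                                  mk_labs, vocab):
        labs = mk_labs([("E1", "bnp", 650, "serum", D1)])
        meds = mk_meds([("E1", "furosemide", "iv", D2)])
        out = cardiac_clinical(meds, labs, one_sirs, vocab)
        assert not out["chf"].iloc[0]

    def test_vasopressor_in_window_is_cardiac_failure(self, one_sirs, mk_meds,
                                                      vocab):
        meds = mk_meds([("E1", "norepinephrine", "iv", D1)])
        out = cardiac_clinical(meds, empty_table("labs"), one_sirs, vocab)
        assert out["cardiac_failure"].iloc[0]

    def test_abnormal_troponin_is_cardiac_stress(self, one_sirs, mk_labs,
                                                 vocab):
        labs = mk_labs([("E1", "troponin", 0.06, "serum", D1)])
        out = cardiac_clinical(empty_table("med_orders"), labs, one_sirs, vocab)
        assert out["cardiac_stress"].iloc[0]


class TestHemorrhage:
    def test_hgb_drop_over_20_within_24h(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "hemoglobin", 120, "serum", D1),
                        ("E1", "hemoglobin", 95, "serum",
                         "2012-03-03 20:00")])
        out = hemorrhage_clinical(labs, empty_table("procedures"),
                                  empty_table("med_orders"), one_sirs, vocab)
        assert out["hgb_drop"].iloc[0]

    def test_slow_hgb_decline_does_not_count(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "hemoglobin", 120, "serum", D0),
                        ("E1", "hemoglobin", 95, "serum", D2)])  # 48 h apart
        out = hemorrhage_clinical(labs, empty_table("procedures"),
                                  empty_table("med_orders"), one_sirs, vocab)
        assert not out["hgb_drop"].iloc[0]

    def test_thrombocytopenia_is_coagulopathy(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "platelets", 140, "serum", D1)])
        out = hemorrhage_clinical(labs, empty_table("procedures"),
                                  empty_table("med_orders"), one_sirs, vocab)
        assert out["coagulopathy"].iloc[0]

    def test_high_inr_on_warfarin_is_excluded(self, one_sirs, mk_labs,
                                              mk_meds, vocab):
        labs = mk_labs([("E1", "pt_inr", 2.5, "serum", D1)])
        meds = mk_meds([("E1", "warfarin", "oral", D0)])
        out = hemorrhage_clinical(labs, empty_table("procedures"), meds,
                                  one_sirs, vocab)
        assert not out["coagulopathy"].iloc[0]
        out = hemorrhage_clinical(labs, empty_table("procedures"),
                                  empty_table("med_orders"), one_sirs, vocab)
        assert out["coagulopathy"].iloc[0]

    def test_transfusion_via_procedure_code(self, one_sirs, vocab):
        procs = pd.DataFrame([{"encounter_id": "E1", "icd9_code": "99.04",
                               "sequence": 1.0,
                               "datetime": pd.Timestamp(D1)}])
        out = hemorrhage_clinical(empty_table("labs"), procs,
                                  empty_table("med_orders"), one_sirs, vocab)
        assert out["transfusion"].iloc[0]


class TestInfection:
    def cultures(self, specimen, when="2012-03-05"):
        return pd.DataFrame([{"encounter_id": "E1", "specimen": specimen,
                              "result_date": pd.Timestamp(when),
                              "positive": "True"}])

    def test_blood_culture_with_wbc_and_antibiotic_is_sepsis(self, one_sirs,
                                                             mk_labs, mk_meds,
                                                             vocab):
        labs = mk_labs([("E1", "wbc", 13.0, "serum", "2012-03-05 09:00")])
        meds = mk_meds([("E1", "vancomycin", "iv", "2012-03-06 09:00")])
        out = infection_clinical(self.cultures("blood"), labs, meds,
                                 one_sirs, vocab)
        assert out["sepsis"].iloc[0]

    def test_normal_wbc_blocks_the_flag(self, one_sirs, mk_labs, mk_meds,
                                        vocab):
        labs = mk_labs([("E1", "wbc", 9.0, "serum", "2012-03-05 09:00")])
        meds = mk_meds([("E1", "vancomycin", "iv", "2012-03-06 09:00")])
        out = infection_clinical(self.cultures("blood"), labs, meds,
                                 one_sirs, vocab)
        assert not out["sepsis"].iloc[0]

    def test_antibiotic_before_culture_does_not_count(self, one_sirs, mk_labs,
                                                      mk_meds, vocab):
        labs = mk_labs([("E1", "wbc", 13.0, "serum", "2012-03-05 09:00")])
        meds = mk_meds([("E1", "vancomycin", "iv", "2012-03-03 09:00")])
        out = infection_clinical(self.cultures("blood"), labs, meds,
                                 one_sirs, vocab)
        assert not out["sepsis"].iloc[0]

    def test_urine_culture_maps_to_uti(self, one_sirs, mk_labs, mk_meds,
                                       vocab):
        labs = mk_labs([("E1", "wbc", 13.0, "serum", "2012-03-04 09:00")])
        meds = mk_meds([("E1", "ceftriaxone", "iv", "2012-03-05 09:00")])
        out = infection_clinical(self.cultures("urine"), labs, meds,
                                 one_sirs, vocab)
        assert out["uti"].iloc[0] and not out["sepsis"].iloc[0]


class TestElectrolytesAcidosis:
    def test_low_k_with_replacement(self, one_sirs, mk_labs, mk_meds, vocab):
        labs = mk_labs([("E1", "potassium", 3.2, "serum", D1)])
        meds = mk_meds([("E1", "potassium chloride", "oral", D1)])
        out = electrolyte_flags(labs, meds, one_sirs, vocab)
        assert out["low_potassium"].iloc[0]
        assert out["low_potassium_replacement"].iloc[0]

    def test_replacement_never_fires_without_low_flag(self, one_sirs, mk_labs,
                                                      mk_meds, vocab):
        labs = mk_labs([("E1", "potassium", 4.2, "serum", D1)])
        meds = mk_meds([("E1", "potassium chloride", "oral", D1)])
        out = electrolyte_flags(labs, meds, one_sirs, vocab)
        assert not out["low_potassium_replacement"].iloc[0]

    def test_high_potassium_threshold_strict(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "potassium", 5.5, "serum", D1),
                        ("E1", "potassium", 5.0, "serum", D2)])
        out = electrolyte_flags(labs, empty_table("med_orders"), one_sirs,
                                vocab)
        assert out["high_potassium"].iloc[0]
        labs = mk_labs([("E1", "potassium", 5.0, "serum", D1)])
        out = electrolyte_flags(labs, empty_table("med_orders"), one_sirs,
                                vocab)
        assert not out["high_potassium"].iloc[0]

    def test_all_in_range_all_false(self, one_sirs, mk_labs, vocab):
        labs = mk_labs([("E1", "potassium", 4.2, "serum", D1),
                        ("E1", "sodium", 140, "serum", D1),
                        ("E1", "magnesium", 0.85, "serum", D1),
                        ("E1", "ionized_calcium", 1.2, "serum", D1)])
        out = electrolyte_flags(labs, empty_table("med_orders"), one_sirs,
                                vocab)
        flags = [c for c in out.columns if c != "encounter_id"]
        assert not out[flags].any(axis=None)

    def test_hyperchloremic_acidosis_needs_both_conditions(self, one_sirs,
                                                           mk_labs):
        labs = mk_labs([("E1", "arterial_ph", 7.30, "arterial", D1),
                        ("E1", "chloride", 112, "serum", D1)])
        out = acidosis_flags(labs, one_sirs)
        assert out["hyperchloremic_acidosis"].iloc[0]
        labs = mk_labs([("E1", "arterial_ph", 7.40, "arterial", D1),
                        ("E1", "chloride", 115, "serum", D1)])
        out = acidosis_flags(labs, one_sirs)
        assert not out["hyperchloremic_acidosis"].iloc[0]

    def test_metabolic_acidosis(self, one_sirs, mk_labs):
        labs = mk_labs([("E1", "arterial_ph", 7.30, "arterial", D1),
                        ("E1", "bicarbonate", 18, "serum", D1)])
        out = acidosis_flags(labs, one_sirs)
        assert out["metabolic_acidosis"].iloc[0]

    def test_venous_lactate_counts_for_lactic_acidosis(self, one_sirs,
                                                       mk_labs):
        labs = mk_labs([("E1", "lactate", 2.5, "venous", D1)])
        out = acidosis_flags(labs, one_sirs)
        assert out["lactic_acidosis"].iloc[0]
        assert out["lactate_ordered"].iloc[0]

    def test_normal_lactate_still_marks_lactate_ordered(self, one_sirs,
                                                        mk_labs):
        labs = mk_labs([("E1", "lactate", 1.2, "venous", D1)])
        out = acidosis_flags(labs, one_sirs)
        assert not out["lactic_acidosis"].iloc[0]
        assert out["lactate_ordered"].iloc[0]


class TestEndpoints:
    def encounters(self, rows):
        return pd.DataFrame(
            [{"encounter_id": r[0], "patient_id": r[1],
              "admit_datetime": pd.Timestamp(r[2]),
              "discharge_datetime": pd.Timestamp(r[3]),
              "discharge_status": r[4], "admission_source": "emergency",
              "admission_type": "emergency", "payor": "other",
              "bed_size": "200-399", "urban": "yes", "teaching": "yes",
              "region": "northeast"} for r in rows])

    def test_expired_status_and_fractional_los(self):
        enc = self.encounters(
            [("E1", "P1", "2012-01-01 00:00", "2012-01-05 12:00", "expired")])
        ep = encounter_endpoints(enc, enc[["encounter_id", "patient_id"]])
        assert ep["died_in_hospital"].iloc[0]
        assert ep["los_days"].iloc[0] == pytest.approx(4.5)

    def test_readmission_windows_nest(self):
        enc = self.encounters(
            [("E1", "P1", "2012-01-01 08:00", "2012-01-05 08:00", "home"),
             ("E2", "P1", "2012-02-19 08:00", "2012-02-21 08:00", "home")])
        ep = encounter_endpoints(enc, enc.iloc[:1][["encounter_id",
                                                    "patient_id"]])
        row = ep.iloc[0]  # readmitted 45 days after discharge
        assert not row["readmitted_30"]
        assert row["readmitted_60"] and row["readmitted_90"]

    def test_nesting_invariant_on_simulated_bundle(self, small_sim, vocab):
        bundle, _ = small_sim
        sirs = sf.detect_sirs(bundle.vitals, bundle.labs)
        idx = bundle.encounters[
            bundle.encounters["encounter_id"].isin(sirs["encounter_id"])]
        ep = encounter_endpoints(bundle.encounters,
                                 idx[["encounter_id", "patient_id"]])
        assert (~ep["readmitted_30"] | ep["readmitted_60"]).all()
        assert (~ep["readmitted_60"] | ep["readmitted_90"]).all()


def test_every_flag_false_on_empty_bundle(one_sirs, vocab):
    """Missing-assumed-normal: no data can never assert an outcome."""
    empty = sf.empty_bundle()
    parts = [
        cardiac_clinical(empty.med_orders, empty.labs, one_sirs, vocab),
        hemorrhage_clinical(empty.labs, empty.procedures, empty.med_orders,
                            one_sirs, vocab),
        infection_clinical(empty.cultures, empty.labs, empty.med_orders,
                           one_sirs, vocab),
        gi_clinical(empty.diagnoses, one_sirs, vocab),
        electrolyte_flags(empty.labs, empty.med_orders, one_sirs, vocab),
        acidosis_flags(empty.labs, one_sirs),
    ]
    for p in parts:
        flags = [c for c in p.columns if c != "encounter_id"]
        assert not p[flags].any(axis=None)


def test_flag_computation_invariant_to_record_order(one_sirs, mk_labs,
                                                    mk_meds, vocab):
    labs = mk_labs([("E1", "potassium", 3.2, "serum", D1),
                    ("E1", "potassium", 4.0, "serum", D2),
                    ("E1", "sodium", 133, "serum", D1)])
    meds = mk_meds([("E1", "potassium chloride", "oral", D1)])
    a = electrolyte_flags(labs, meds, one_sirs, vocab)
    b = electrolyte_flags(labs.iloc[::-1].reset_index(drop=True), meds,
                          one_sirs, vocab)
    pd.testing.assert_frame_equal(a, b)
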