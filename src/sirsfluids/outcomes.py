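"""Outcome adjudication: administrative codes, clinical definitions, endpoints.

Administrative outcomes are ICD-9 diagnosis categories counted only when the
code is not flagged present-on-admission.  Clinical outcomes are operational
definitions over labs, medication orders and cultures.  Encounter endpoints
are in-hospital death, fractional length of stay, and 30/60/90-day
readmission.

Observation windows: the cardiac definitions use qualification day through
day +3 as stated by their definitions; lab/med-based flags without a stated
window (electrolytes, acidosis, hemorrhage, infection) use the full index
stay.  Missing data are assumed normal, so every flag is false on an empty
bundle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import EHRBundle, day_of, most_abnormal
from .vocab import VocabularyConfig

CARDIAC_WINDOW_DAYS = (0, 3)

ELECTROLYTE_RANGES = {  # analyte -> (low, high), canonical mmol/L
    "magnesium": (0.70, 1.0),
    "potassium": (3.5, 5.0),
    "sodium": (136.0, 145.0),
    "ionized_calcium": (1.1, 1.4),
}
_REPLACEMENT_CLASS = {"magnesium": "iv_magnesium",
                      "potassium": "potassium_iv_or_oral",
                      "ionized_calcium": "iv_calcium"}


def _normalize_codes(s: pd.Series) -> pd.Series:
    return s.astype(str).str.replace(".", "", regex=False).str.upper()


def _prefix_hit(codes: pd.Series, prefixes: list[str]) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=codes.index)
    pat = "|".join(sorted(prefixes, key=len, reverse=True))
    return codes.str.match(f"(?:{pat})")


def _flag_frame(index, names) -> pd.DataFrame:
    return pd.DataFrame({n: pd.Series(False, index=index) for n in names})


def _classed_meds(meds: pd.DataFrame, vocab: VocabularyConfig) -> pd.DataFrame:
    m = meds.copy()
    m["drug_class"] = [vocab.drug_class(d) for d in m["drug"]]
    return m


def admin_outcomes(diagnoses: pd.DataFrame, vocab: VocabularyConfig,
                   encounter_ids: pd.Series) -> pd.DataFrame:
    """Administrative outcome booleans: category true iff any code in the
    category's set carries poa='no' (an 'unknown' flag counts as not present
    on admission, the conservative direction for outcome counting)."""
    cats = list(vocab.admin_outcomes)
    out = _flag_frame(encounter_ids, cats)
    out.insert(0, "encounter_id", encounter_ids.to_numpy())
    out = out.set_index("encounter_id")
    if diagnoses.empty:
        return out.reset_index()
    dx = diagnoses[diagnoses["poa_flag"].str.lower().isin(["no", "unknown", "n", "u"])]
    if dx.empty:
        return out.reset_index()
    codes = _normalize_codes(dx["icd9_code"])
    for cat in cats:
        hit = dx.loc[_prefix_hit(codes, vocab.admin_outcomes[cat]),
                     "encounter_id"].unique()
        out.loc[out.index.intersection(hit), cat] = True
    return out.reset_index()


def _window_filter(df: pd.DataFrame, qual: pd.Series, time_col: str,
                   window: tuple[int, int] | None) -> pd.DataFrame:
    d = df.merge(qual.rename("qdate"), left_on="encounter_id",
                 right_index=True, how="inner")
    if window is None:
        return d
    off = (day_of(d[time_col]) - d["qdate"]).dt.days
    return d[(off >= window[0]) & (off <= window[1])]


def cardiac_clinical(meds: pd.DataFrame, labs: pd.DataFrame,
                     sirs: pd.DataFrame, vocab: VocabularyConfig,
                     window: tuple[int, int] = CARDIAC_WINDOW_DAYS) -> pd.DataFrame:
    """Cardiac clinical flags.

    dysrhythmia: IV antiarrhythmic infusion in days 0..+3;
    cardiac_stress: troponin above the configured upper limit;
    chf: (echocardiogram order or BNP >600 pg/mL) with same-day diuretic use;
    cardiac_failure: vasopressor use in days 0..+3.
    """
    idx = sirs["encounter_id"]
    out = _flag_frame(idx, ["dysrhythmia", "cardiac_stress", "chf",
                            "cardiac_failure"])
    out.insert(0, "encounter_id", idx.to_numpy())
    out = out.set_index("encounter_id")
    qual = sirs.set_index("encounter_id")["qualification_date"]

    if not meds.empty:
        m = _classed_meds(meds, vocab)
        aa = _window_filter(m[(m["drug_class"] == "antiarrhythmic_iv")
                              & (m["route"].str.lower() == "iv")],
                            qual, "datetime", window)
        out.loc[out.index.intersection(aa["encounter_id"].unique()),
                "dysrhythmia"] = True
        vaso = _window_filter(m[m["drug_class"] == "vasopressor"],
                              qual, "datetime", window)
        out.loc[out.index.intersection(vaso["encounter_id"].unique()),
                "cardiac_failure"] = True

    if not labs.empty:
        trop = labs[labs["analyte"] == "troponin"]
        uln = vocab.thresholds["troponin_uln_ng_ml"]
        hit = trop.loc[trop["value"] > uln, "encounter_id"].unique()
        out.loc[out.index.intersection(hit), "cardiac_stress"] = True

    # CHF: (ECHO order or BNP>600) AND a diuretic order on the same day
    triggers = []
    if not labs.empty:
        bnp = labs[(labs["analyte"] == "bnp")
                   & (labs["value"] > vocab.thresholds["bnp_chf_pg_ml"])]
        if not bnp.empty:
            triggers.append(bnp[["encounter_id", "datetime"]])
    if not meds.empty and vocab.echo_order_names:
        names = [n.lower() for n in vocab.echo_order_names]
        echo = meds[meds["drug"].str.lower().isin(names)]
        if not echo.empty:
            triggers.append(echo[["encounter_id", "datetime"]])
    if triggers and not meds.empty:
        trig = pd.concat(triggers, ignore_index=True)
        trig["day"] = day_of(trig["datetime"])
        m = _classed_meds(meds, vocab)
        diu = m[m["drug_class"] == "diuretic"].copy()
        if not diu.empty:
            diu["day"] = day_of(diu["datetime"])
            hit = trig.merge(diu[["encounter_id", "day"]].drop_duplicates(),
                             on=["encounter_id", "day"])
            out.loc[out.index.intersection(hit["encounter_id"].unique()),
                    "chf"] = True
    return out.reset_index()


def hemorrhage_clinical(labs: pd.DataFrame, procedures: pd.DataFrame,
                        meds: pd.DataFrame, sirs: pd.DataFrame,
                        vocab: VocabularyConfig) -> pd.DataFrame:
    """Hemorrhage/hematologic flags over the index stay.

    hgb_drop: any hemoglobin decline >20 g/L between readings <=24 h apart;
    transfusion: ICD-9 procedure-code set;
    coagulopathy: (INR above threshold with no warfarin order) or platelets
    <150 x10^9/L or D-dimer above threshold.
    """
    idx = sirs["encounter_id"]
    out = _flag_frame(idx, ["hgb_drop", "transfusion", "coagulopathy"])
    out.insert(0, "encounter_id", idx.to_numpy())
    out = out.set_index("encounter_id")

    if not labs.empty:
        hgb = labs[labs["analyte"] == "hemoglobin"]
        for eid, grp in hgb.groupby("encounter_id"):
            if len(grp) < 2 or eid not in out.index:
                continue
            g = grp.sort_values("datetime")
            t = g["datetime"].to_numpy()
            v = g["value"].to_numpy()
            for j in range(1, len(v)):
                back = (t[j] - t[:j]) <= np.timedelta64(24, "h")
                if back.any() and v[:j][back].max() - v[j] > 20.0:
                    out.loc[eid, "hgb_drop"] = True
                    break

        warf_ids: set = set()
        if not meds.empty:
            m = _classed_meds(meds, vocab)
            warf_ids = set(m.loc[m["drug_class"] == "warfarin", "encounter_id"])
        inr = labs[(labs["analyte"] == "pt_inr")
                   & (labs["value"] > vocab.thresholds["inr_abnormal"])]
        inr_ids = set(inr["encounter_id"]) - warf_ids
        plt_ids = set(labs.loc[(labs["analyte"] == "platelets")
                               & (labs["value"] < 150.0), "encounter_id"])
        dd_ids = set(labs.loc[(labs["analyte"] == "d_dimer")
                              & (labs["value"] > vocab.thresholds["d_dimer_uln_ng_ml"]),
                              "encounter_id"])
        hit = (inr_ids | plt_ids | dd_ids) & set(out.index)
        out.loc[sorted(hit), "coagulopathy"] = True

    if not procedures.empty:
        codes = _normalize_codes(procedures["icd9_code"])
        hit = procedures.loc[_prefix_hit(codes, vocab.procedure_sets["transfusion"]),
                             "encounter_id"].unique()
        out.loc[out.index.intersection(hit), "transfusion"] = True
    return out.reset_index()


def infection_clinical(cultures: pd.DataFrame, labs: pd.DataFrame,
                       meds: pd.DataFrame, sirs: pd.DataFrame,
                       vocab: VocabularyConfig) -> pd.DataFrame:
    """Culture-anchored infection flags per specimen type.

    Each flag requires a positive culture, WBC >12 x10^9/L within +/-1
    calendar day of the culture date, and an antibiotic order from the
    culture day through day +3.
    """
    specimen_map = {"tracheal_aspirate_or_bal": "pneumonia",
                    "blood": "sepsis", "urine": "uti", "line": "line_infection"}
    idx = sirs["encounter_id"]
    out = _flag_frame(idx, list(specimen_map.values()))
    out.insert(0, "encounter_id", idx.to_numpy())
    out = out.set_index("encounter_id")
    if cultures.empty:
        return out.reset_index()
    pos = cultures[~cultures["positive"].astype(str).str.lower()
                   .isin(["false", "0", "no"])].copy()
    if pos.empty:
        return out.reset_index()
    pos["cday"] = day_of(pos["result_date"])

    wbc = labs[labs["analyte"] == "wbc"].copy() if not labs.empty else labs
    abx = pd.DataFrame()
    if not meds.empty:
        m = _classed_meds(meds, vocab)
        abx = m[m["drug_class"] == "antibiotic"].copy()
    if wbc.empty or abx.empty:
        return out.reset_index()
    wbc["day"] = day_of(wbc["datetime"])
    abx["day"] = day_of(abx["datetime"])

    wbc_hi = wbc[wbc["value"] > 12.0][["encounter_id", "day"]]
    c = pos.merge(wbc_hi, on="encounter_id")
    c = c[(c["day"] - c["cday"]).dt.days.abs() <= 1]
    c = c[["encounter_id", "specimen", "cday"]].drop_duplicates()
    c = c.merge(abx[["encounter_id", "day"]], on="encounter_id")
    off = (c["day"] - c["cday"]).dt.days
    c = c[(off >= 0) & (off <= 3)]
    for (eid, spec) in c[["encounter_id", "specimen"]].drop_duplicates().itertuples(index=False):
        flag = specimen_map.get(spec)
        if flag and eid in out.index:
            out.loc[eid, flag] = True
    return out.reset_index()


def gi_clinical(diagnoses: pd.DataFrame, sirs: pd.DataFrame,
                vocab: VocabularyConfig) -> pd.DataFrame:
    """Acute cholecystitis via its (non-POA) diagnosis code set."""
    idx = sirs["encounter_id"]
    out = _flag_frame(idx, ["cholecystitis"])
    out.insert(0, "encounter_id", idx.to_numpy())
    out = out.set_index("encounter_id")
    if not diagnoses.empty:
        dx = diagnoses[diagnoses["poa_flag"].str.lower().isin(
            ["no", "unknown", "n", "u"])]
        codes = _normalize_codes(dx["icd9_code"])
        hit = dx.loc[_prefix_hit(codes, vocab.diagnosis_sets["cholecystitis"]),
                     "encounter_id"].unique()
        out.loc[out.index.intersection(hit), "cholecystitis"] = True
    return out.reset_index()


def electrolyte_flags(labs: pd.DataFrame, meds: pd.DataFrame,
                      sirs: pd.DataFrame, vocab: VocabularyConfig) -> pd.DataFrame:
    """Low/high flags per monitored electrolyte plus replacement flags.

    Uses the most abnormal reading over the stay; a replacement flag fires
    only when the low flag does and a matching replacement order exists.
    """
    idx = sirs["encounter_id"]
    names = []
    for a in ELECTROLYTE_RANGES:
        names += [f"low_{a}", f"high_{a}"]
        if a in _REPLACEMENT_CLASS:
            names.append(f"low_{a}_replacement")
    out = _flag_frame(idx, names)
    out.insert(0, "encounter_id", idx.to_numpy())
    out = out.set_index("encounter_id")

    repl_ids: dict[str, set] = {a: set() for a in _REPLACEMENT_CLASS}
    if not meds.empty:
        m = _classed_meds(meds, vocab)
        for a, cls in _REPLACEMENT_CLASS.items():
            repl_ids[a] = set(m.loc[m["drug_class"] == cls, "encounter_id"])

    if not labs.empty:
        for a, (lo, hi) in ELECTROLYTE_RANGES.items():
            sub = labs[labs["analyte"] == a]
            for eid, grp in sub.groupby("encounter_id"):
                if eid not in out.index:
                    continue
                low_fired, _ = most_abnormal(grp["value"], lo, "below")
                high_fired, _ = most_abnormal(grp["value"], hi, "above")
                out.loc[eid, f"low_{a}"] = low_fired
                out.loc[eid, f"high_{a}"] = high_fired
                if a in _REPLACEMENT_CLASS and low_fired and eid in repl_ids[a]:
                    out.loc[eid, f"low_{a}_replacement"] = True
    return out.reset_index()


def acidosis_flags(labs: pd.DataFrame, sirs: pd.DataFrame) -> pd.DataFrame:
    """Acidosis flags: hyperchloremic (arterial pH <7.35 and chloride
    >110 mmol/L), metabolic (arterial pH <7.35 and bicarbonate <22 mmol/L),
    lactic (venous or arterial lactate >2.0 mmol/L); plus lactate_ordered."""
    idx = sirs["encounter_id"]
    out = _flag_frame(idx, ["hyperchloremic_acidosis", "metabolic_acidosis",
                            "lactic_acidosis", "lactate_ordered"])
    out.insert(0, "encounter_id", idx.to_numpy())
    out = out.set_index("encounter_id")
    if labs.empty:
        return out.reset_index()
    art_ph = labs[(labs["analyte"] == "arterial_ph")
                  & (labs["specimen"].str.lower() == "arterial")]
    low_ph = set(art_ph.loc[art_ph["value"] < 7.35, "encounter_id"])
    hi_cl = set(labs.loc[(labs["analyte"] == "chloride")
                         & (labs["value"] > 110.0), "encounter_id"])
    lo_bicarb = set(labs.loc[(labs["analyte"] == "bicarbonate")
                             & (labs["value"] < 22.0), "encounter_id"])
    lact = labs[(labs["analyte"] == "lactate")
                & (labs["specimen"].str.lower().isin(["arterial", "venous"]))]
    hi_lact = set(lact.loc[lact["value"] > 2.0, "encounter_id"])
    members = set(out.index)
    out.loc[sorted((low_ph & hi_cl) & members), "hyperchloremic_acidosis"] = True
    out.loc[sorted((low_ph & lo_bicarb) & members), "metabolic_acidosis"] = True
    out.loc[sorted(hi_lact & members), "lactic_acidosis"] = True
    out.loc[sorted(set(lact["encounter_id"]) & members), "lactate_ordered"] = True
    return out.reset_index()


def encounter_endpoints(encounters: pd.DataFrame,
                        index_encounters: pd.DataFrame) -> pd.DataFrame:
    """Death, LOS and readmission endpoints for each index encounter.

    ``index_encounters`` needs encounter_id and patient_id columns.
    Readmission at N days: another admission for the same patient starting
    within N days after the index discharge.
    """
    idx = index_encounters[["encounter_id", "patient_id"]].copy()
    enc = encounters.set_index("encounter_id")
    sub = enc.reindex(idx["encounter_id"])
    out = idx.copy()
    out["died_in_hospital"] = (sub["discharge_status"].str.lower()
                               == "expired").to_numpy()
    out["los_days"] = ((sub["discharge_datetime"] - sub["admit_datetime"])
                       .dt.total_seconds() / 86400.0).to_numpy()
    for n in (30, 60, 90):
        out[f"readmitted_{n}"] = False
    others = encounters.merge(idx, on="patient_id", suffixes=("", "_index"))
    others = others[others["encounter_id"] != others["encounter_id_index"]]
    if not others.empty:
        disc = sub["discharge_datetime"]
        others = others.assign(
            gap=(others["admit_datetime"]
                 - others["encounter_id_index"].map(disc)).dt.total_seconds() / 86400.0)
        others = others[others["gap"] > 0]
        out = out.set_index("encounter_id")
        for n in (30, 60, 90):
            hit = others.loc[others["gap"] <= n, "encounter_id_index"].unique()
            out.loc[out.index.intersection(hit), f"readmitted_{n}"] = True
        out = out.reset_index()
    return out


def adjudicate_all(bundle: EHRBundle, sirs: pd.DataFrame,
                   cohort_table: pd.DataFrame, vocab: VocabularyConfig,
                   phenotypes: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """All outcome flags and endpoints for the cohort's index encounters."""
    sub_sirs = sirs[sirs["encounter_id"].isin(cohort_table["encounter_id"])]
    parts = [
        admin_outcomes(bundle.diagnoses, vocab, sub_sirs["encounter_id"]),
        cardiac_clinical(bundle.med_orders, bundle.labs, sub_sirs, vocab),
        hemorrhage_clinical(bundle.labs, bundle.procedures, bundle.med_orders,
                            sub_sirs, vocab),
        infection_clinical(bundle.cultures, bundle.labs, bundle.med_orders,
                           sub_sirs, vocab),
        gi_clinical(bundle.diagnoses, sub_sirs, vocab),
        electrolyte_flags(bundle.labs, bundle.med_orders, sub_sirs, vocab),
        acidosis_flags(bundle.labs, sub_sirs),
    ]
    out = parts[0]
    for p in parts[1:]:
        out = out.merge(p, on="encounter_id", how="outer")
    if phenotypes is not None:
        kd = phenotypes["kdigo"][["encounter_id", "stage"]].rename(
            columns={"stage": "kdigo_stage"})
        out = out.merge(kd, on="encounter_id", how="left")
        out["kdigo_stage"] = out["kdigo_stage"].fillna(0).astype(int)
        out["aki"] = out["kdigo_stage"] >= 1
    ep = encounter_endpoints(bundle.encounters,
                             cohort_table[["encounter_id", "patient_id"]])
    return out.merge(ep.drop(columns="patient_id"), on="encounter_id", how="left")
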