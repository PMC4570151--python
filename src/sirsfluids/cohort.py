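"""Cohort construction: eligibility, fluid exposure, cohort assignment.

The comparison is between encounters whose early resuscitation fluid was
predominantly 0.9% saline versus a calcium-free balanced crystalloid.
Fluid accounting follows calendar-day windows relative to the SIRS
qualification day: the qualifying window is days 0-2 ("within 48 hours")
and the total window days 0-3 ("72 hours following").  Bags of <=250 mL are
ignored everywhere (drug-admixture carriers), and only the four monitored
non-dextrose crystalloids enter volume sums and chloride loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import EHRBundle, day_of
from .vocab import VocabularyConfig
from .phenotype import phenotype_bundle

MIN_BAG_ML = 250.0          # strict: bags must exceed this to count
QUALIFYING_VOLUME_L = 0.5   # inclusive: >=500 mL of the cohort fluid
PRIOR_DAY_LIMIT_L = 1.0     # strict: >1 L on day -1 excludes
MIN_AGE_YEARS = 18.0
MIN_LOS_HOURS = 24.0

EXCLUSION_REASONS = ["age", "los", "no_qualifying_fluid", "prior_day_fluid",
                     "cardiac_surgery", "esrd", "colloid_or_hypertonic"]


@dataclass
class Funnel:
    """Cohort-selection funnel counts."""
    screened: int = 0
    sirs: int = 0
    fluid_qualified: int = 0
    eligible: int = 0
    balanced: int = 0
    saline: int = 0
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("screened", "sirs", "fluid_qualified", "eligible",
              "balanced", "saline")}
        d.update({f"excluded_{k}": v for k, v in self.exclusion_counts.items()})
        return d


def fluid_exposure(fluid_orders: pd.DataFrame, sirs: pd.DataFrame,
                   vocab: VocabularyConfig,
                   qual_window: tuple[int, int] = (0, 2),
                   total_window: tuple[int, int] = (0, 3)) -> pd.DataFrame:
    """Per-encounter crystalloid volumes (L) and chloride loads (mmol).

    Returns one row per SIRS-qualified encounter with, for each monitored
    crystalloid type, the qualifying-window and total-window volume, the
    total-window chloride load, the overall totals, the volume-weighted mean
    delivered chloride concentration (NaN when no fluid counted), the
    prior-day (day -1) crystalloid volume, and a colloid/hypertonic receipt
    flag (any order at any time, any bag size).
    """
    crys = vocab.crystalloid_types
    out = sirs[["encounter_id"]].copy()
    for f in crys:
        out[f"vol_{f}_qual_l"] = 0.0
        out[f"vol_{f}_total_l"] = 0.0
        out[f"chloride_{f}_mmol"] = 0.0
    out["total_volume_l"] = 0.0
    out["chloride_load_mmol"] = 0.0
    out["mean_chloride_mmol_per_l"] = np.nan
    out["prior_day_volume_l"] = 0.0
    out["any_colloid_or_hypertonic"] = False
    if out.empty or fluid_orders.empty:
        return out
    out = out.set_index("encounter_id")

    qual = sirs.set_index("encounter_id")["qualification_date"]
    fo = fluid_orders.merge(qual.rename("qdate"), left_on="encounter_id",
                            right_index=True, how="inner")
    unknown = set(fo["fluid_type"]) - set(vocab.fluid_chloride)
    if unknown:
        from .vocab import VocabularyError
        raise VocabularyError(f"unknown fluid type(s): {sorted(unknown)}")

    ch = (fo[fo["fluid_type"].isin(["colloid", "hypertonic_saline"])]
          ["encounter_id"].unique())
    out.loc[[e for e in ch if e in out.index], "any_colloid_or_hypertonic"] = True

    fo = fo[fo["bag_volume_ml"] > MIN_BAG_ML]
    fo = fo[fo["fluid_type"].isin(crys)]
    if fo.empty:
        return out.reset_index()
    fo = fo.assign(offset=(day_of(fo["datetime"]) - fo["qdate"]).dt.days,
                   vol_l=fo["bag_volume_ml"] / 1000.0)

    prior = (fo[fo["offset"] == -1].groupby("encounter_id")["vol_l"].sum())
    out.loc[prior.index, "prior_day_volume_l"] = prior

    for lo, hi, tag in [(qual_window[0], qual_window[1], "qual"),
                        (total_window[0], total_window[1], "total")]:
        w = fo[(fo["offset"] >= lo) & (fo["offset"] <= hi)]
        vols = w.groupby(["encounter_id", "fluid_type"])["vol_l"].sum().unstack()
        for f in crys:
            if f in getattr(vols, "columns", []):
                v = vols[f].dropna()
                out.loc[v.index, f"vol_{f}_{tag}_l"] = v

    for f in crys:
        out[f"chloride_{f}_mmol"] = (out[f"vol_{f}_total_l"]
                                     * vocab.chloride_mmol_per_l(f))
    vol_cols = [f"vol_{f}_total_l" for f in crys]
    cl_cols = [f"chloride_{f}_mmol" for f in crys]
    out["total_volume_l"] = out[vol_cols].sum(axis=1)
    out["chloride_load_mmol"] = out[cl_cols].sum(axis=1)
    nz = out["total_volume_l"] > 0
    out.loc[nz, "mean_chloride_mmol_per_l"] = (
        out.loc[nz, "chloride_load_mmol"] / out.loc[nz, "total_volume_l"])
    return out.reset_index()


def assign_cohort(exposure: pd.DataFrame) -> pd.Series:
    """Cohort label per encounter: 'balanced', 'saline' or None.

    Balanced: >=0.5 L calcium-free balanced crystalloid in the qualifying
    window (receipt of saline does not block membership).  Saline: >=0.5 L
    0.9% saline in the qualifying window AND zero balanced volume anywhere in
    the total window.  The balanced rule is evaluated first, so an encounter
    qualifying for both is balanced.
    """
    bal = exposure["vol_calcium_free_balanced_qual_l"] >= QUALIFYING_VOLUME_L
    sal = ((exposure["vol_saline_09_qual_l"] >= QUALIFYING_VOLUME_L)
           & (exposure["vol_calcium_free_balanced_total_l"] == 0))
    lab = pd.Series([None] * len(exposure), index=exposure.index, dtype=object)
    lab[sal] = "saline"
    lab[bal] = "balanced"
    lab.index = exposure["encounter_id"].values
    return lab.where(lab.notna(), None)


def apply_eligibility(encounters: pd.DataFrame, patients: pd.DataFrame,
                      bundle: EHRBundle, sirs: pd.DataFrame,
                      exposure: pd.DataFrame, vocab: VocabularyConfig,
                      cohort: pd.Series | None = None) -> pd.DataFrame:
    """Evaluate every inclusion/exclusion rule per SIRS-qualified encounter.

    All violated rules are reported (no short-circuit): age <18 years,
    length of stay <24 h, no qualifying fluid (no cohort label), >1 L
    crystalloid on the day before qualification, cardiac surgery (procedure
    code set), end-stage renal disease (diagnosis code set), and receipt of
    any colloid or hypertonic saline.

    Returns (encounter_id, eligible, reasons) where ``reasons`` is a list of
    exclusion codes in the fixed order of :data:`EXCLUSION_REASONS`.
    """
    if cohort is None:
        cohort = assign_cohort(exposure)
    idx = sirs["encounter_id"]
    enc = encounters.set_index("encounter_id").reindex(idx)
    pat = patients.set_index("patient_id")
    age = enc["patient_id"].map(pat["age"])
    los_h = (enc["discharge_datetime"] - enc["admit_datetime"]).dt.total_seconds() / 3600.0
    exp = exposure.set_index("encounter_id").reindex(idx)

    def code_hit(df, codesets):
        if df.empty or not codesets:
            return pd.Series(False, index=idx)
        codes = df["icd9_code"].astype(str).str.replace(".", "", regex=False)
        pat_re = "|".join(sorted(codesets, key=len, reverse=True))
        hit = df.loc[codes.str.match(f"(?:{pat_re})"), "encounter_id"].unique()
        return pd.Series(idx.isin(hit).to_numpy(), index=idx)

    flags = pd.DataFrame(index=idx)
    flags["age"] = (age < MIN_AGE_YEARS).to_numpy()
    flags["los"] = (los_h < MIN_LOS_HOURS).to_numpy()
    flags["no_qualifying_fluid"] = cohort.reindex(idx).isna().to_numpy()
    flags["prior_day_fluid"] = (exp["prior_day_volume_l"] > PRIOR_DAY_LIMIT_L).to_numpy()
    flags["cardiac_surgery"] = code_hit(bundle.procedures,
                                        vocab.procedure_sets.get("cardiac_surgery", []))
    flags["esrd"] = code_hit(bundle.diagnoses, vocab.diagnosis_sets.get("esrd", []))
    flags["colloid_or_hypertonic"] = exp["any_colloid_or_hypertonic"].fillna(False).to_numpy()

    flag_arr = flags[EXCLUSION_REASONS].to_numpy(dtype=bool)
    names = np.array(EXCLUSION_REASONS, dtype=object)
    reasons = [list(names[row]) for row in flag_arr]
    return pd.DataFrame({
        "encounter_id": idx.to_numpy(),
        "eligible": ~flag_arr.any(axis=1),
        "reasons": reasons,
    })


# covariates carried into the propensity model, per the matched-table design
DEMOGRAPHIC_COVARIATES = ["age", "gender", "race"]
HOSPITAL_COVARIATES = ["bed_size", "admission_source", "admission_type",
                       "payor", "urban", "teaching", "region"]


def build_cohort_table(bundle: EHRBundle, vocab: VocabularyConfig,
                       phenotypes: dict[str, pd.DataFrame] | None = None
                       ) -> tuple[pd.DataFrame, Funnel]:
    """Assemble one row per eligible, cohort-assigned encounter.

    Runs SIRS detection, fluid exposure, eligibility and cohort assignment,
    then merges demographics, hospital attributes, Elixhauser booleans and
    the APS.  Only each patient's first qualifying encounter is kept.
    Returns the cohort table and the selection :class:`Funnel`.
    """
    if phenotypes is None:
        phenotypes = phenotype_bundle(bundle, vocab)
    sirs = phenotypes["sirs"]
    funnel = Funnel(screened=len(bundle.encounters), sirs=len(sirs))

    exposure = fluid_exposure(bundle.fluid_orders, sirs, vocab)
    cohort = assign_cohort(exposure)
    elig = apply_eligibility(bundle.encounters, bundle.patients, bundle,
                             sirs, exposure, vocab, cohort=cohort)
    funnel.fluid_qualified = int(cohort.notna().sum())
    for reason in EXCLUSION_REASONS:
        funnel.exclusion_counts[reason] = int(
            elig["reasons"].map(lambda r: reason in r).sum())

    keep = elig.loc[elig["eligible"], "encounter_id"]
    df = sirs[sirs["encounter_id"].isin(keep)][
        ["encounter_id", "qualification_date"]].copy()
    df["cohort"] = cohort.reindex(df["encounter_id"]).to_numpy()

    enc_cols = ["encounter_id", "patient_id", "admit_datetime",
                "discharge_datetime", "discharge_status"] + HOSPITAL_COVARIATES
    df = df.merge(bundle.encounters[enc_cols], on="encounter_id", how="left")
    df = df.merge(bundle.patients[["patient_id"] + DEMOGRAPHIC_COVARIATES],
                  on="patient_id", how="left")

    # first qualifying encounter per patient only
    df = (df.sort_values(["admit_datetime", "encounter_id"])
            .groupby("patient_id", as_index=False).first())

    elix = phenotypes["elixhauser"]
    comorb_cols = [c for c in elix.columns if c != "encounter_id"]
    df = df.merge(elix, on="encounter_id", how="left")
    df[comorb_cols] = df[comorb_cols].where(
        df[comorb_cols].notna(), False).astype(bool)
    df = df.merge(phenotypes["aps"][["encounter_id", "aps"]],
                  on="encounter_id", how="left")
    df["aps"] = df["aps"].fillna(0).astype(int)
    exp_cols = ["encounter_id", "total_volume_l", "chloride_load_mmol",
                "mean_chloride_mmol_per_l"]
    df = df.merge(exposure[exp_cols], on="encounter_id", how="left")

    funnel.eligible = len(df)
    funnel.balanced = int((df["cohort"] == "balanced").sum())
    funnel.saline = int((df["cohort"] == "saline").sum())
    return df.reset_index(drop=True), funnel
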