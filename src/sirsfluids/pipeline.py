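"""End-to-end orchestration: bundle -> phenotypes -> cohort -> match -> effects.

One call, :func:`run_study`, chains every stage the way the comparative-
effectiveness analysis prescribes: SIRS phenotyping, cohort construction,
propensity fitting with backward elimination, digit-greedy 1:1 matching,
balance diagnostics, outcome adjudication on the matched set, and
unadjusted plus APS-and-residual-covariate-adjusted odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import EHRBundle
from .vocab import VocabularyConfig, load_vocab
from .phenotype import phenotype_bundle
from .cohort import build_cohort_table, Funnel, DEMOGRAPHIC_COVARIATES, \
    HOSPITAL_COVARIATES
from .matching import (fit_propensity, greedy_match, balance_table,
                       residual_covariates, build_design, MatchResult,
                       PropensityModel, EstimationError)
from .outcomes import adjudicate_all, encounter_endpoints
from .effects import (estimate_outcome_table, fluid_summary_table,
                      build_report, TwoByTwo, or_2x2, EffectResult)

DEFAULT_OUTCOME_COLS = [
    "cardiac", "hemorrhage", "infectious", "gastrointestinal", "neurologic",
    "acute_renal_failure", "respiratory_failure", "new_organ_failure",
    "died_in_hospital", "readmitted_30", "readmitted_60", "readmitted_90",
    "dysrhythmia", "cardiac_stress", "chf", "cardiac_failure", "hgb_drop",
    "transfusion", "coagulopathy", "pneumonia", "sepsis", "uti",
    "line_infection", "cholecystitis", "aki",
    "low_magnesium_replacement", "high_magnesium",
    "low_potassium_replacement", "high_potassium",
    "low_sodium", "high_sodium", "low_ionized_calcium_replacement",
    "lactic_acidosis", "metabolic_acidosis", "hyperchloremic_acidosis",
]


@dataclass
class StudyResult:
    cohort_table: pd.DataFrame
    funnel: Funnel
    propensity: PropensityModel | None
    match: MatchResult | None
    balance: pd.DataFrame | None
    outcomes: pd.DataFrame | None
    effect_table: pd.DataFrame | None
    report: dict | None


def propensity_covariates(cohort_table: pd.DataFrame) -> list[str]:
    """Candidate covariates: demographics, hospital attributes, comorbidities."""
    fixed = DEMOGRAPHIC_COVARIATES + HOSPITAL_COVARIATES
    skip = set(fixed) | {
        "encounter_id", "patient_id", "cohort", "qualification_date",
        "admit_datetime", "discharge_datetime", "discharge_status", "aps",
        "total_volume_l", "chloride_load_mmol", "mean_chloride_mmol_per_l"}
    comorb = [c for c in cohort_table.columns if c not in skip
              and cohort_table[c].dtype == bool]
    return [c for c in fixed if c in cohort_table.columns] + comorb


def matched_mortality_or(bundle: EHRBundle,
                         vocab: VocabularyConfig | None = None,
                         seed: int = 0,
                         covariates: list[str] | None = None
                         ) -> tuple[EffectResult, MatchResult]:
    """Lean replicate path: cohort -> propensity -> 1:1 match -> mortality OR.

    Runs the same stages as :func:`run_study` but adjudicates only the
    in-hospital-death endpoint on the matched set, for use in repeated
    simulation experiments.
    """
    if vocab is None:
        vocab = load_vocab()
    phen = {"sirs": None}
    from .phenotype import detect_sirs, map_elixhauser, compute_aps
    sirs = detect_sirs(bundle.vitals, bundle.labs)
    phen = {"sirs": sirs,
            "elixhauser": map_elixhauser(bundle.diagnoses, vocab),
            "aps": compute_aps(bundle.labs, bundle.vitals, sirs)}
    cohort_df, _ = build_cohort_table(bundle, vocab, phenotypes=phen)
    covs = covariates if covariates is not None \
        else propensity_covariates(cohort_df)
    model = fit_propensity(cohort_df, covs)
    labels = cohort_df.set_index("encounter_id")["cohort"]
    match = greedy_match(model.scores, labels, seed=seed)
    matched = cohort_df[cohort_df["encounter_id"].isin(match.matched_ids())]
    ep = encounter_endpoints(bundle.encounters,
                             matched[["encounter_id", "patient_id"]])
    died = ep.set_index("encounter_id")["died_in_hospital"]
    lab = matched.set_index("encounter_id")["cohort"]
    a = int(died[lab == "balanced"].sum())
    c = int(died[lab == "saline"].sum())
    t = TwoByTwo.from_events(a, int((lab == "balanced").sum()),
                             c, int((lab == "saline").sum()))
    return or_2x2(t, outcome="died_in_hospital"), match


def run_study(bundle: EHRBundle, vocab: VocabularyConfig | None = None,
              seed: int = 0, outcome_cols: list[str] | None = None,
              covariates: list[str] | None = None,
              outdir=None) -> StudyResult:
    """Run the full matched comparative-effectiveness analysis on a bundle."""
    if vocab is None:
        vocab = load_vocab()
    phen = phenotype_bundle(bundle, vocab)
    cohort_df, funnel = build_cohort_table(bundle, vocab, phenotypes=phen)
    if cohort_df.empty or cohort_df["cohort"].nunique() < 2:
        return StudyResult(cohort_df, funnel, None, None, None, None, None,
                           build_report(None, None, None, outdir=outdir))

    covs = covariates if covariates is not None \
        else propensity_covariates(cohort_df)
    model = fit_propensity(cohort_df, covs)
    labels = cohort_df.set_index("encounter_id")["cohort"]
    match = greedy_match(model.scores, labels, seed=seed)
    balance = balance_table(cohort_df, covs, match)

    matched_ids = match.matched_ids()
    matched = cohort_df[cohort_df["encounter_id"].isin(matched_ids)]
    out_df = adjudicate_all(bundle, phen["sirs"], matched, vocab,
                            phenotypes=phen)
    out_df = out_df.set_index("encounter_id").reindex(
        matched["encounter_id"]).reset_index()

    cols = outcome_cols if outcome_cols is not None else \
        [c for c in DEFAULT_OUTCOME_COLS if c in out_df.columns]
    labels_m = matched.set_index("encounter_id")["cohort"].reindex(
        out_df["encounter_id"])
    aps = matched.set_index("encounter_id")["aps"].reindex(
        out_df["encounter_id"])
    resid = residual_covariates(balance)
    adjusters = None
    if resid:
        adjusters = build_design(matched, resid).reindex(out_df["encounter_id"])
    out_idx = out_df.set_index("encounter_id")
    effect_table = estimate_outcome_table(out_idx, labels_m, cols,
                                          aps=aps, adjusters=adjusters)
    fluids = fluid_summary_table(matched)
    report = build_report(balance, fluids, effect_table, outdir=outdir)
    return StudyResult(cohort_df, funnel, model, match, balance, out_df,
                       effect_table, report)
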