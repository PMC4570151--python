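"""Synthetic EHR bundles with known ground truth.

The generator emits the same linked tables the loader consumes, with the
statistical structure the analysis assumes: SIRS-triggering physiology
(tachycardia plus one secondary criterion on a qualification day),
confounded fluid-type assignment through a configurable logistic model,
and outcomes drawn from logistic models with known treatment log-odds
ratios, so every downstream stage can be tested against planted truth.

The default configuration emulates the study conditions of the source
cohort: ~2% of assigned patients receive the calcium-free balanced
crystalloid, baseline in-hospital mortality ~3%, APS-like latent severity
entering both physiology and outcomes, and deliberate boundary cases
(<=250 mL bags, 499/500 mL totals, >1 L prior-day fluid, under-age and
short-stay encounters) at low rates.  Everything is driven by a single
seeded generator: a fixed config+seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import EHRBundle, empty_bundle, write_bundle

_BASE_DATE = pd.Timestamp("2012-01-01")

# representative ICD-9 code per simulated comorbidity (dots stripped)
COMORBIDITY_CODES = {
    "congestive_heart_failure": "4280",
    "hypertension": "4019",
    "chronic_pulmonary": "496",
    "diabetes_uncomplicated": "25000",
    "hypothyroidism": "2449",
    "obesity": "2780",
    "depression": "311",
    "liver_disease": "5715",
    "renal_failure": "5859",
    "deficiency_anemias": "2819",
}

ADMIN_OUTCOME_CODES = {"cardiac_admin": "42731", "renal_admin": "5849"}


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SynthConfig:
    """Parameters of the synthetic EHR generator.

    Covariate names usable in ``treatment['coefficients']`` and in each
    outcome model's ``coefficients`` are the comorbidity categories plus
    ``male``, ``teaching`` and ``age_c`` (age centered at 50, per decade).
    ``treatment_log_or`` in an outcome model is the planted causal effect of
    receiving balanced fluid on that outcome's log-odds.
    """
    n_patients: int = 20000
    seed: int = 0
    sirs_prevalence: float = 0.5
    age_band_probs: dict = field(default_factory=lambda: {
        "18-35": 0.17, "36-50": 0.19, "51-64": 0.26, "65-80": 0.27,
        "80+": 0.11})
    female_prob: float = 0.56
    race_probs: dict = field(default_factory=lambda: {
        "white": 0.74, "black": 0.12, "other": 0.14})
    hospital: dict = field(default_factory=lambda: {
        "bed_size": {"0-199": 0.10, "200-399": 0.42, "400+": 0.48},
        "urban_prob": 0.985,
        "teaching_prob": 0.865,
        "region": {"northeast": 0.63, "south": 0.11, "west": 0.26},
        "admission_source": {"emergency": 0.01, "healthcare_facility": 0.06,
                             "non_healthcare_facility": 0.73, "other": 0.20},
        "admission_type": {"elective": 0.54, "emergency": 0.46},
        "payor": {"commercial": 0.15, "medicare_medicaid": 0.37,
                  "other": 0.48}})
    comorbidity_prevalence: dict = field(default_factory=lambda: {
        "congestive_heart_failure": 0.031, "hypertension": 0.196,
        "chronic_pulmonary": 0.085, "diabetes_uncomplicated": 0.075,
        "hypothyroidism": 0.036, "obesity": 0.079, "depression": 0.074,
        "liver_disease": 0.012, "renal_failure": 0.026,
        "deficiency_anemias": 0.046})
    severity: dict = field(default_factory=lambda: {"shape": 2.0, "scale": 2.4})
    treatment: dict = field(default_factory=lambda: {
        "intercept": _logit(0.02),
        "coefficients": {"hypertension": 0.25,
                         "congestive_heart_failure": -0.25},
        "severity_coef": 0.0})
    outcomes: dict = field(default_factory=lambda: {
        "mortality": {"intercept": _logit(0.03),
                      "treatment_log_or": float(np.log(0.38)),
                      "severity_coef": 0.12, "coefficients": {}},
        "low_potassium": {"intercept": _logit(0.13),
                          "treatment_log_or": float(np.log(0.50)),
                          "severity_coef": 0.03, "coefficients": {}},
        "hyperchloremic_acidosis": {"intercept": _logit(0.033),
                                    "treatment_log_or": float(np.log(0.35)),
                                    "severity_coef": 0.05, "coefficients": {}},
        "readmission_90": {"intercept": _logit(0.16),
                           "treatment_log_or": float(np.log(0.73)),
                           "severity_coef": 0.02, "coefficients": {}},
        "cardiac_admin": {"intercept": _logit(0.08),
                          "treatment_log_or": float(np.log(0.49)),
                          "severity_coef": 0.05, "coefficients": {}}})
    los: dict = field(default_factory=lambda: {
        "log_mean": float(np.log(4.0)), "log_sd": 0.55,
        "treatment_effect": -0.10, "severity_coef": 0.03})
    fluids: dict = field(default_factory=lambda: {
        "bag_volumes_ml": [500.0, 1000.0], "bag_volume_probs": [0.4, 0.6],
        "extra_bags_mean": 1.4,
        "extra_mix_balanced": {"calcium_free_balanced": 0.45, "saline_09": 0.35,
                               "lactated_ringers": 0.15, "saline_045": 0.05},
        "extra_mix_saline": {"saline_09": 0.60, "lactated_ringers": 0.30,
                             "saline_045": 0.10}})
    boundary: dict = field(default_factory=lambda: {
        "sub500_prob": 0.02, "small_bag_prob": 0.04,
        "prior_day_gt1l_prob": 0.01, "prior_day_exact1l_prob": 0.005,
        "colloid_prob": 0.01, "esrd_prob": 0.004,
        "cardiac_surgery_prob": 0.004})
    underage_prob: float = 0.015
    short_stay_prob: float = 0.02
    labs_detail: bool = True
    readmission_enabled: bool = True

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        probs = ([self.sirs_prevalence, self.female_prob, self.underage_prob,
                  self.short_stay_prob]
                 + list(self.comorbidity_prevalence.values())
                 + list(self.boundary.values()))
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability out of [0,1]: {p}")
        for dist in (self.age_band_probs, self.race_probs):
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ConfigError("distribution probabilities must sum to 1")
        known = self.covariate_names()
        for name in self.treatment.get("coefficients", {}):
            if name not in known:
                raise ConfigError(f"unknown treatment covariate: {name!r}")
        for out, model in self.outcomes.items():
            for name in model.get("coefficients", {}):
                if name not in known:
                    raise ConfigError(
                        f"unknown covariate {name!r} in outcome {out!r}")

    def covariate_names(self) -> list[str]:
        return list(self.comorbidity_prevalence) + ["male", "teaching", "age_c"]


def default_config(n_patients: int = 20000, seed: int = 0) -> SynthConfig:
    return SynthConfig(n_patients=n_patients, seed=seed)


def recovery_config(treatment_or: float, n_patients: int = 20000,
                    seed: int = 0) -> SynthConfig:
    """Lean null-confounding scenario for effect-recovery experiments.

    Everyone develops SIRS on the admission day, arms are assigned 50:50
    independent of covariates, baseline mortality is 15% so matched 2x2
    cells are well populated, and all boundary-case injections are off.
    """
    cfg = SynthConfig(n_patients=n_patients, seed=seed)
    cfg.sirs_prevalence = 1.0
    cfg.treatment = {"intercept": 0.0, "coefficients": {}, "severity_coef": 0.0}
    cfg.outcomes = {"mortality": {"intercept": _logit(0.15),
                                  "treatment_log_or": float(np.log(treatment_or)),
                                  "severity_coef": 0.0, "coefficients": {}}}
    cfg.comorbidity_prevalence = {"hypertension": 0.2,
                                  "congestive_heart_failure": 0.05}
    cfg.boundary = {k: 0.0 for k in cfg.boundary}
    cfg.underage_prob = 0.0
    cfg.short_stay_prob = 0.0
    cfg.labs_detail = False
    cfg.readmission_enabled = False
    cfg.fluids = dict(cfg.fluids, extra_bags_mean=0.3)
    return cfg


def inject_confounding(config: SynthConfig, covariate: str,
                       assignment_log_odds: float,
                       outcome_log_odds: float,
                       outcome: str = "mortality") -> SynthConfig:
    """Return a config where ``covariate`` shifts both the balanced-fluid
    assignment odds and the named outcome's odds, biasing the crude OR away
    from the planted treatment OR."""
    if covariate not in config.covariate_names():
        raise ConfigError(f"unknown covariate: {covariate!r}")
    if outcome not in config.outcomes:
        raise ConfigError(f"unknown outcome: {outcome!r}")
    cfg = copy.deepcopy(config)
    cfg.treatment.setdefault("coefficients", {})[covariate] = assignment_log_odds
    cfg.outcomes[outcome].setdefault("coefficients", {})[covariate] = outcome_log_odds
    return cfg


def _choice(rng, options: dict, n: int) -> np.ndarray:
    keys = list(options)
    p = np.array([options[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=n, p=p)


_AGE_RANGES = {"0-17": (12, 17), "18-35": (18, 35), "36-50": (36, 50),
               "51-64": (51, 64), "65-80": (65, 80), "80+": (81, 95)}


def simulate_bundle(config: SynthConfig) -> tuple[EHRBundle, pd.DataFrame]:
    """Generate a synthetic bundle plus its per-encounter truth table.

    The truth table has one row per simulated index encounter with the
    latent assignments: SIRS status, latent severity, the exact assignment
    probability (``true_propensity``), intended arm, and each configured
    outcome's realized indicator.
    """
    config.validate()
    n = config.n_patients
    if n == 0:
        truth = pd.DataFrame(columns=["patient_id", "encounter_id", "sirs",
                                      "severity", "true_propensity",
                                      "treatment"])
        return empty_bundle(), truth
    rng = np.random.default_rng(config.seed)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    eid = np.array([f"E{i:06d}" for i in range(n)])

    band = _choice(rng, config.age_band_probs, n)
    underage = rng.random(n) < config.underage_prob
    band = np.where(underage, "0-17", band)
    lo = np.array([_AGE_RANGES[b][0] for b in band])
    hi = np.array([_AGE_RANGES[b][1] for b in band])
    age = rng.integers(lo, hi + 1)
    male = rng.random(n) >= config.female_prob
    race = _choice(rng, config.race_probs, n)

    hosp = config.hospital
    bed = _choice(rng, hosp["bed_size"], n)
    urban = np.where(rng.random(n) < hosp["urban_prob"], "yes", "no")
    teaching = rng.random(n) < hosp["teaching_prob"]
    region = _choice(rng, hosp["region"], n)
    adm_src = _choice(rng, hosp["admission_source"], n)
    adm_type = _choice(rng, hosp["admission_type"], n)
    payor = _choice(rng, hosp["payor"], n)

    comorb = {c: rng.random(n) < p
              for c, p in config.comorbidity_prevalence.items()}
    covariates = dict(comorb)
    covariates["male"] = male
    covariates["teaching"] = teaching
    covariates["age_c"] = (age - 50.0) / 10.0

    severity = rng.gamma(config.severity["shape"], config.severity["scale"],
                         size=n)
    sirs = rng.random(n) < config.sirs_prevalence
    short_stay = rng.random(n) < config.short_stay_prob
    qual_offset = rng.choice([0, 1, 2], size=n, p=[0.5, 0.3, 0.2])
    qual_offset = np.where(short_stay, 0, qual_offset)

    def linpred(model: dict) -> np.ndarray:
        lp = np.full(n, model.get("intercept", 0.0))
        for name, beta in model.get("coefficients", {}).items():
            lp = lp + beta * np.asarray(covariates[name], dtype=float)
        lp = lp + model.get("severity_coef", 0.0) * severity
        return lp

    propensity = _sigmoid(linpred(config.treatment))
    treat = rng.random(n) < propensity

    outcome_flags: dict[str, np.ndarray] = {}
    for name, model in config.outcomes.items():
        lp = linpred(model) + model["treatment_log_or"] * treat
        outcome_flags[name] = rng.random(n) < _sigmoid(lp)
    died = outcome_flags.get("mortality", np.zeros(n, dtype=bool))

    admit = (_BASE_DATE
             + pd.to_timedelta(rng.integers(0, 365, n), unit="D")
             + pd.to_timedelta(rng.integers(6, 20, n), unit="h"))
    los_model = config.los
    los_days = np.exp(rng.normal(
        los_model["log_mean"]
        + los_model["treatment_effect"] * treat
        + los_model["severity_coef"] * severity, los_model["log_sd"]))
    los_days = np.maximum(los_days, qual_offset + 1.5)
    los_days = np.where(short_stay, 0.85, los_days)
    discharge = (admit
                 + pd.to_timedelta((los_days * 24).round(2), unit="h")).round("s")
    status = np.where(died, "expired",
                      np.where(rng.random(n) < 0.8, "home", "snf"))
    status = np.where(short_stay & ~died, "home", status)

    admit_day = admit.normalize()
    qual_day = admit_day + pd.to_timedelta(qual_offset, unit="D")

    # ---- vitals -----------------------------------------------------------
    v_eid, v_name, v_val, v_dt = [], [], [], []

    def add_vitals(mask, name, values, day, hour):
        idx = np.flatnonzero(mask)
        v_eid.append(eid[idx])
        v_name.append(np.full(idx.size, name))
        v_val.append(np.asarray(values)[idx] if np.ndim(values) else
                     np.full(idx.size, values))
        v_dt.append(day[idx] + pd.to_timedelta(hour, unit="h"))

    all_mask = np.ones(n, dtype=bool)
    hr_base = rng.uniform(68, 88, n)
    add_vitals(all_mask, "heart_rate", hr_base, admit_day, 9)
    hr_sirs = 91.0 + rng.exponential(12.0, n) + 0.8 * severity
    add_vitals(sirs, "heart_rate", hr_sirs, qual_day, 10)
    secondary = rng.choice(["temperature", "respiratory", "leukocyte"],
                           size=n, p=[0.5, 0.3, 0.2])
    temp_hi = 38.05 + rng.exponential(0.7, n)
    add_vitals(sirs & (secondary == "temperature"), "temperature",
               temp_hi, qual_day, 10)
    rr_hi = 20.0 + rng.poisson(6.0, n)
    add_vitals(sirs & (secondary == "respiratory"), "respiratory_rate",
               rr_hi, qual_day, 11)

    vitals = pd.DataFrame({
        "encounter_id": np.concatenate(v_eid),
        "vital": np.concatenate(v_name),
        "value": np.round(np.concatenate(v_val), 1),
        "datetime": pd.DatetimeIndex(np.concatenate(
            [d.to_numpy() for d in v_dt])),
    })

    # ---- labs -------------------------------------------------------------
    l_eid, l_an, l_val, l_unit, l_spec, l_dt = [], [], [], [], [], []

    def add_labs(mask, analyte, values, unit, specimen, day, hour):
        idx = np.flatnonzero(mask)
        l_eid.append(eid[idx])
        l_an.append(np.full(idx.size, analyte))
        l_val.append(np.asarray(values)[idx])
        l_unit.append(np.full(idx.size, unit))
        l_spec.append(np.full(idx.size, specimen))
        l_dt.append(day[idx] + pd.to_timedelta(hour, unit="h"))

    wbc_hi = 12.0 + rng.exponential(4.0, n)
    add_labs(sirs & (secondary == "leukocyte"), "wbc",
             np.round(wbc_hi, 1), "1e9/L", "serum", qual_day, 8)

    if config.labs_detail:
        creat = np.round(0.65 + 0.07 * severity + rng.normal(0, 0.1, n).clip(-0.2), 2)
        add_labs(sirs, "creatinine", creat.clip(0.3), "mg/dL", "serum",
                 qual_day, 7)
        sod = np.round(rng.normal(139, 3.0, n), 0)
        add_labs(sirs, "sodium", sod, "mmol/L", "serum", qual_day, 7)

    lowk = outcome_flags.get("low_potassium", np.zeros(n, dtype=bool)) & sirs
    k_val = np.where(lowk, rng.uniform(2.9, 3.4, n),
                     np.round(rng.uniform(3.6, 4.8, n), 1))
    if config.labs_detail or lowk.any():
        add_labs(sirs if config.labs_detail else lowk, "potassium",
                 np.round(k_val, 2), "mmol/L", "serum",
                 qual_day + pd.to_timedelta(1, unit="D"), 7)

    hca = outcome_flags.get("hyperchloremic_acidosis",
                            np.zeros(n, dtype=bool)) & sirs
    if hca.any():
        ph = np.round(rng.uniform(7.25, 7.345, n), 2)
        cl = np.round(rng.uniform(111, 122, n), 0)
        add_labs(hca, "arterial_ph", ph, "", "arterial",
                 qual_day + pd.to_timedelta(1, unit="D"), 6)
        add_labs(hca, "chloride", cl, "mmol/L", "serum",
                 qual_day + pd.to_timedelta(1, unit="D"), 6)

    if l_eid:
        labs = pd.DataFrame({
            "encounter_id": np.concatenate(l_eid),
            "analyte": np.concatenate(l_an),
            "value": np.concatenate(l_val).astype(float),
            "unit": np.concatenate(l_unit),
            "specimen": np.concatenate(l_spec),
            "datetime": pd.DatetimeIndex(np.concatenate(
                [d.to_numpy() for d in l_dt])),
        })
    else:
        labs = empty_bundle().labs

    # ---- fluid orders -----------------------------------------------------
    bvols = np.asarray(config.fluids["bag_volumes_ml"], dtype=float)
    bprobs = np.asarray(config.fluids["bag_volume_probs"], dtype=float)
    f_eid, f_type, f_vol, f_dt = [], [], [], []

    bnd = config.boundary
    u = rng.random(n)
    sub500 = sirs & (u < bnd["sub500_prob"])
    edges = np.cumsum([bnd["sub500_prob"], bnd["small_bag_prob"],
                       bnd["prior_day_gt1l_prob"],
                       bnd["prior_day_exact1l_prob"], bnd["colloid_prob"]])
    small_bag = sirs & (u >= edges[0]) & (u < edges[1])
    prior_gt = sirs & (u >= edges[1]) & (u < edges[2])
    prior_eq = sirs & (u >= edges[2]) & (u < edges[3])
    colloid = sirs & (u >= edges[3]) & (u < edges[4])

    def add_fluid(idx, ftype, vol_ml, day, hour):
        f_eid.append(eid[idx])
        f_type.append(ftype if isinstance(ftype, np.ndarray)
                      else np.full(idx.size, ftype))
        f_vol.append(vol_ml if isinstance(vol_ml, np.ndarray)
                     else np.full(idx.size, float(vol_ml)))
        f_dt.append(qual_day[idx] + pd.to_timedelta(day, unit="D")
                    + pd.to_timedelta(hour, unit="h"))

    normal_fluids = sirs & ~sub500
    idx = np.flatnonzero(normal_fluids)
    qual_vol = rng.choice(bvols, size=n, p=bprobs)
    qual_type = np.where(treat, "calcium_free_balanced", "saline_09")
    add_fluid(idx, qual_type[idx], qual_vol[idx], 0, 12)

    # extra bags on days 0-2, drawn from the per-arm fluid mix
    n_extra = rng.poisson(config.fluids["extra_bags_mean"], n)
    n_extra = np.where(sirs & ~sub500, n_extra, 0)
    if n_extra.sum() > 0:
        rep = np.repeat(np.arange(n), n_extra)
        mix_b = config.fluids["extra_mix_balanced"]
        mix_s = config.fluids["extra_mix_saline"]
        pick_b = _choice(rng, mix_b, rep.size)
        pick_s = _choice(rng, mix_s, rep.size)
        etype = np.where(treat[rep], pick_b, pick_s)
        evol = rng.choice(bvols, size=rep.size, p=bprobs)
        eday = rng.choice([0, 1, 2], size=rep.size)
        add_fluid(rep, etype, evol, eday, 14)

    idx = np.flatnonzero(sub500)
    add_fluid(idx, np.where(treat, "calcium_free_balanced", "saline_09")[idx],
              499.0, 0, 12)
    idx = np.flatnonzero(small_bag)
    add_fluid(idx, "saline_09", 250.0, 0, 15)
    idx = np.flatnonzero(prior_gt & (qual_offset >= 1))
    add_fluid(idx, "saline_09", 1100.0, -1, 9)
    idx = np.flatnonzero(prior_eq & (qual_offset >= 1))
    add_fluid(idx, "saline_09", 1000.0, -1, 9)
    idx = np.flatnonzero(colloid)
    add_fluid(idx, "colloid", 500.0, 1, 9)

    if f_eid:
        fluid_orders = pd.DataFrame({
            "encounter_id": np.concatenate(f_eid),
            "fluid_type": np.concatenate(f_type),
            "bag_volume_ml": np.concatenate(f_vol).astype(float),
            "datetime": pd.DatetimeIndex(np.concatenate(
                [d.to_numpy() for d in f_dt])),
        })
    else:
        fluid_orders = empty_bundle().fluid_orders

    # ---- medication orders (electrolyte replacement) ----------------------
    m_eid, m_drug, m_route, m_dt = [], [], [], []
    repl = lowk & (rng.random(n) < 0.85)
    idx = np.flatnonzero(repl)
    if idx.size:
        m_eid.append(eid[idx])
        m_drug.append(np.full(idx.size, "potassium chloride"))
        m_route.append(np.full(idx.size, "oral"))
        m_dt.append(qual_day[idx] + pd.to_timedelta(1, unit="D")
                    + pd.to_timedelta(12, unit="h"))
    if m_eid:
        med_orders = pd.DataFrame({
            "encounter_id": np.concatenate(m_eid),
            "drug": np.concatenate(m_drug),
            "route": np.concatenate(m_route),
            "datetime": pd.DatetimeIndex(np.concatenate(
                [d.to_numpy() for d in m_dt])),
        })
    else:
        med_orders = empty_bundle().med_orders

    # ---- diagnoses / procedures ------------------------------------------
    d_eid, d_code, d_poa = [], [], []
    for cat, flags in comorb.items():
        idx = np.flatnonzero(flags)
        d_eid.append(eid[idx])
        d_code.append(np.full(idx.size, COMORBIDITY_CODES[cat]))
        d_poa.append(np.full(idx.size, "yes"))
    cardiac_admin = outcome_flags.get("cardiac_admin",
                                      np.zeros(n, dtype=bool)) & sirs
    idx = np.flatnonzero(cardiac_admin)
    d_eid.append(eid[idx])
    d_code.append(np.full(idx.size, ADMIN_OUTCOME_CODES["cardiac_admin"]))
    d_poa.append(np.full(idx.size, "no"))
    esrd = sirs & (rng.random(n) < bnd["esrd_prob"])
    idx = np.flatnonzero(esrd)
    d_eid.append(eid[idx])
    d_code.append(np.full(idx.size, "5856"))
    d_poa.append(np.full(idx.size, "yes"))
    diag_eid = np.concatenate(d_eid)
    diagnoses = pd.DataFrame({
        "encounter_id": diag_eid,
        "icd9_code": np.concatenate(d_code),
        "poa_flag": np.concatenate(d_poa),
        "sequence": np.ones(diag_eid.size),
    }) if diag_eid.size else empty_bundle().diagnoses

    csurg = sirs & (rng.random(n) < bnd["cardiac_surgery_prob"])
    idx = np.flatnonzero(csurg)
    procedures = pd.DataFrame({
        "encounter_id": eid[idx],
        "icd9_code": np.full(idx.size, "3961"),
        "sequence": np.ones(idx.size),
        "datetime": pd.DatetimeIndex(qual_day[idx]
                                     + pd.to_timedelta(20, unit="h")),
    }) if idx.size else empty_bundle().procedures

    # ---- readmission encounters ------------------------------------------
    readmit = (outcome_flags.get("readmission_90", np.zeros(n, dtype=bool))
               & ~died & sirs)
    if not config.readmission_enabled:
        readmit = np.zeros(n, dtype=bool)
    gap = 1 + rng.geometric(1 / 35.0, n).clip(1, 89)
    r_idx = np.flatnonzero(readmit)
    readmit_gap = np.where(readmit, gap, -1)

    encounters = pd.DataFrame({
        "encounter_id": eid, "patient_id": pid,
        "admit_datetime": admit, "discharge_datetime": discharge,
        "discharge_status": status,
        "admission_source": adm_src, "admission_type": adm_type,
        "payor": payor, "bed_size": bed, "urban": urban,
        "teaching": np.where(teaching, "yes", "no"), "region": region,
    })
    if r_idx.size:
        r_admit = discharge[r_idx] + pd.to_timedelta(gap[r_idx], unit="D")
        r_enc = pd.DataFrame({
            "encounter_id": np.array([f"R{i:06d}" for i in r_idx]),
            "patient_id": pid[r_idx],
            "admit_datetime": r_admit,
            "discharge_datetime": r_admit + pd.to_timedelta(3, unit="D"),
            "discharge_status": np.full(r_idx.size, "home"),
            "admission_source": adm_src[r_idx],
            "admission_type": np.full(r_idx.size, "emergency"),
            "payor": payor[r_idx], "bed_size": bed[r_idx],
            "urban": urban[r_idx],
            "teaching": np.where(teaching[r_idx], "yes", "no"),
            "region": region[r_idx],
        })
        encounters = pd.concat([encounters, r_enc], ignore_index=True)

    patients = pd.DataFrame({
        "patient_id": pid, "age": age.astype(float),
        "gender": np.where(male, "male", "female"), "race": race,
    })

    bundle = EHRBundle(
        patients=patients, encounters=encounters, vitals=vitals, labs=labs,
        fluid_orders=fluid_orders, med_orders=med_orders,
        diagnoses=diagnoses, procedures=procedures,
        cultures=empty_bundle().cultures,
    )

    truth = pd.DataFrame({
        "patient_id": pid, "encounter_id": eid, "sirs": sirs,
        "severity": severity, "true_propensity": propensity,
        "treatment": np.where(treat, "balanced", "saline"),
        "qual_offset": qual_offset, "los_days": los_days,
        "readmit_gap_days": readmit_gap,
    })
    for name, flags in outcome_flags.items():
        truth[name] = flags
    return bundle, truth


# ---------------------------------------------------------------------------
# Fixtures

def boundary_bundle() -> EHRBundle:
    """Deterministic hand-built bundle exercising every cohort boundary rule.

    Sixteen encounters cover the 499/500 mL and 250/251 mL bag boundaries,
    the >1 L prior-day rule, age and length-of-stay bounds, colloid/ESRD/
    cardiac-surgery exclusions, the balanced-fluid-on-day-3 saline block,
    and two non-qualifying SIRS patterns.  The funnel is hand-enumerable:
    16 screened, 14 SIRS, 12 fluid-qualified, 6 eligible (5 saline,
    1 balanced).
    """
    day = pd.Timestamp("2012-03-01")

    def enc(i, age=50.0, los_h=120.0):
        return {"i": i, "age": age, "los_h": los_h}

    specs = [enc(1), enc(2), enc(3), enc(4), enc(5), enc(6), enc(7), enc(8),
             enc(9), enc(10, age=17.0), enc(11, los_h=20.0), enc(12), enc(13),
             enc(14), enc(15), enc(16)]
    patients, encounters, vitals, fluids, diagnoses, procedures = [], [], [], [], [], []

    def vital(i, name, value, d, h=10):
        vitals.append({"encounter_id": f"B{i:02d}", "vital": name,
                       "value": value, "datetime": day + pd.Timedelta(days=d, hours=h)})

    def fluid(i, ftype, ml, d, h=12):
        fluids.append({"encounter_id": f"B{i:02d}", "fluid_type": ftype,
                       "bag_volume_ml": ml,
                       "datetime": day + pd.Timedelta(days=d, hours=h)})

    for s in specs:
        i = s["i"]
        patients.append({"patient_id": f"PB{i:02d}", "age": s["age"],
                         "gender": "female", "race": "white"})
        admit = day + pd.Timedelta(hours=8)
        encounters.append({
            "encounter_id": f"B{i:02d}", "patient_id": f"PB{i:02d}",
            "admit_datetime": admit,
            "discharge_datetime": admit + pd.Timedelta(hours=s["los_h"]),
            "discharge_status": "home", "admission_source": "emergency",
            "admission_type": "emergency", "payor": "other",
            "bed_size": "200-399", "urban": "yes", "teaching": "yes",
            "region": "northeast"})

    # SIRS on day 1 for everyone except B11 (day 0, short stay), B13, B14
    for i in range(1, 17):
        if i in (13, 14):
            continue
        d = 0 if i == 11 else 1
        vital(i, "heart_rate", 100.0, d)
        vital(i, "temperature", 38.6, d)
    vital(13, "heart_rate", 95.0, 0)   # tachycardia alone: no SIRS
    vital(13, "heart_rate", 95.0, 1)
    vital(14, "heart_rate", 90.0, 1)   # HR exactly 90: strict bound
    vital(14, "temperature", 39.0, 1)

    fluid(1, "saline_09", 1000.0, 1)                 # plain saline cohort
    fluid(2, "calcium_free_balanced", 600.0, 1)      # balanced cohort
    fluid(2, "saline_09", 500.0, 2)                  # saline receipt allowed
    fluid(3, "saline_09", 499.0, 1)                  # below 500: no cohort
    fluid(4, "saline_09", 500.0, 1)                  # exactly 500: saline
    fluid(5, "saline_09", 1000.0, 1)
    fluid(5, "saline_09", 250.0, 1, h=15)            # <=250 mL bag ignored
    fluid(6, "saline_09", 251.0, 1)                  # two 251 mL bags count
    fluid(6, "saline_09", 251.0, 1, h=16)
    fluid(7, "saline_09", 1200.0, 0)                 # day before qual: >1 L
    fluid(7, "saline_09", 1000.0, 1)
    fluid(8, "saline_09", 1000.0, 0)                 # exactly 1 L prior day
    fluid(8, "saline_09", 1000.0, 1)
    fluid(9, "saline_09", 1000.0, 1)
    fluid(9, "colloid", 500.0, 2)                    # colloid receipt
    fluid(10, "saline_09", 1000.0, 1)                # under-age
    fluid(11, "saline_09", 1000.0, 0)                # short stay
    fluid(12, "saline_09", 600.0, 1)                 # balanced on day 3 blocks
    fluid(12, "saline_09", 600.0, 2)
    fluid(12, "saline_09", 600.0, 3)
    fluid(12, "calcium_free_balanced", 500.0, 4)     # day 3 after qual day 1
    fluid(15, "calcium_free_balanced", 500.0, 1)     # balanced but ESRD
    fluid(16, "saline_09", 1000.0, 1)                # cardiac surgery

    diagnoses.append({"encounter_id": "B15", "icd9_code": "5856",
                      "poa_flag": "yes", "sequence": 1.0})
    procedures.append({"encounter_id": "B16", "icd9_code": "3961",
                       "sequence": 1.0,
                       "datetime": day + pd.Timedelta(days=2)})

    base = empty_bundle()
    return EHRBundle(
        patients=pd.DataFrame(patients),
        encounters=pd.DataFrame(encounters),
        vitals=pd.DataFrame(vitals),
        labs=base.labs,
        fluid_orders=pd.DataFrame(fluids),
        med_orders=base.med_orders,
        diagnoses=pd.DataFrame(diagnoses),
        procedures=pd.DataFrame(procedures),
        cultures=base.cultures,
    )


def make_fixtures(outdir) -> dict[str, Path]:
    """Write the named scenario bundles used by tests: 'null' (no boundary
    cases, no confounding), 'confounded' (planted assignment+outcome
    confounder), and 'boundary' (the hand-built rule-boundary bundle)."""
    outdir = Path(outdir)
    written = {}

    cfg = default_config(n_patients=400, seed=7)
    cfg.boundary = {k: 0.0 for k in cfg.boundary}
    cfg.underage_prob = 0.0
    cfg.short_stay_prob = 0.0
    bundle, truth = simulate_bundle(cfg)
    d = outdir / "null"
    write_bundle(bundle, d)
    truth.to_csv(d / "truth.csv", index=False)
    written["null"] = d

    cfg = default_config(n_patients=2000, seed=8)
    cfg.treatment["intercept"] = _logit(0.3)
    cfg = inject_confounding(cfg, "hypertension", 1.5, -1.0)
    bundle, truth = simulate_bundle(cfg)
    d = outdir / "confounded"
    write_bundle(bundle, d)
    truth.to_csv(d / "truth.csv", index=False)
    written["confounded"] = d

    d = outdir / "boundary"
    write_bundle(boundary_bundle(), d)
    written["boundary"] = d
    return written
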