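"""Phenotyping: SIRS qualification and severity/comorbidity scoring.

Implements the modified SIRS definition (tachycardia required, plus at least
one of the temperature, respiratory or leukocyte criteria on the same
calendar day), the APACHE-II Acute Physiology Score (APS), the Elixhauser
comorbidity mapping with the three mutual-exclusivity modifications, SOFA
organ subscores, and creatinine-only KDIGO staging of acute kidney injury.

Everywhere, an absent measurement is assumed normal: it can never satisfy a
SIRS criterion, contributes 0 APS/SOFA points, and yields KDIGO stage 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import EHRBundle, day_of
from .vocab import VocabularyConfig

# ---------------------------------------------------------------------------
# SIRS detection

SIRS_HR_BPM = 90.0            # strict: HR > 90
SIRS_TEMP_HIGH_C = 38.0       # strict: > 38
SIRS_TEMP_LOW_C = 36.0        # strict: < 36
SIRS_RR_MIN = 20.0            # inclusive: >= 20
SIRS_PACO2_MMHG = 32.0        # inclusive: <= 32
SIRS_WBC_HIGH = 12.0          # inclusive: >= 12 x10^9/L
SIRS_WBC_LOW = 4.0            # inclusive: <= 4 x10^9/L


@dataclass(frozen=True)
class SIRSEvent:
    encounter_id: str
    qualification_date: pd.Timestamp
    criteria_met: frozenset[str]


def detect_sirs(vitals: pd.DataFrame, labs: pd.DataFrame,
                encounter_id: str | None = None):
    """Find each encounter's earliest SIRS qualification day.

    Qualification requires, on one calendar day, heart rate >90 bpm plus at
    least one of: temperature >38 or <36 degC; respiratory rate >=20 /min or
    PaCO2 <=32 mmHg; WBC >=12 or <=4 x10^9/L.

    Returns a DataFrame (encounter_id, qualification_date, tachycardia,
    temperature, respiratory, leukocyte), one row per qualifying encounter —
    or, when ``encounter_id`` is given, a single :class:`SIRSEvent` or None.
    """
    frames = []
    if not vitals.empty:
        v = vitals[["encounter_id", "vital", "value"]].copy()
        v["day"] = day_of(vitals["datetime"])
        piv = (v.pivot_table(index=["encounter_id", "day"], columns="vital",
                             values="value", aggfunc=["max", "min"]))
        flags = pd.DataFrame(index=piv.index)
        def col(stat, name):
            if (stat, name) in piv.columns:
                return piv[(stat, name)]
            return pd.Series(np.nan, index=piv.index)
        flags["tachycardia"] = col("max", "heart_rate") > SIRS_HR_BPM
        flags["temperature"] = ((col("max", "temperature") > SIRS_TEMP_HIGH_C)
                                | (col("min", "temperature") < SIRS_TEMP_LOW_C))
        flags["respiratory"] = col("max", "respiratory_rate") >= SIRS_RR_MIN
        frames.append(flags)
    if not labs.empty:
        keep = labs["analyte"].isin(["wbc", "paco2"])
        if keep.any():
            l = labs.loc[keep, ["encounter_id", "analyte", "value"]].copy()
            l["day"] = day_of(labs.loc[keep, "datetime"])
            piv = l.pivot_table(index=["encounter_id", "day"],
                                columns="analyte", values="value",
                                aggfunc=["max", "min"])
            flags = pd.DataFrame(index=piv.index)
            def lcol(stat, name):
                if (stat, name) in piv.columns:
                    return piv[(stat, name)]
                return pd.Series(np.nan, index=piv.index)
            flags["leukocyte"] = ((lcol("max", "wbc") >= SIRS_WBC_HIGH)
                                  | (lcol("min", "wbc") <= SIRS_WBC_LOW))
            flags["respiratory_paco2"] = lcol("min", "paco2") <= SIRS_PACO2_MMHG
            frames.append(flags)

    cols = ["tachycardia", "temperature", "respiratory", "leukocyte"]
    if not frames:
        out = pd.DataFrame(columns=["encounter_id", "qualification_date"] + cols)
    else:
        day = pd.concat(frames, axis=1)
        day = day.where(day.notna(), False).astype(bool)
        for c in cols + ["respiratory_paco2"]:
            if c not in day.columns:
                day[c] = False
        day["respiratory"] = day["respiratory"] | day["respiratory_paco2"]
        n_other = day[["temperature", "respiratory", "leukocyte"]].sum(axis=1)
        qual = day[day["tachycardia"] & (n_other >= 1)]
        if qual.empty:
            out = pd.DataFrame(columns=["encounter_id", "qualification_date"] + cols)
        else:
            qual = qual.reset_index().rename(columns={"day": "qualification_date"})
            qual = (qual.sort_values(["encounter_id", "qualification_date"])
                        .groupby("encounter_id", as_index=False).first())
            out = qual[["encounter_id", "qualification_date"] + cols]
    if encounter_id is None:
        return out.reset_index(drop=True)
    row = out[out["encounter_id"] == encounter_id]
    if row.empty:
        return None
    r = row.iloc[0]
    met = frozenset(c for c in cols if r[c])
    return SIRSEvent(encounter_id, r["qualification_date"], met)


# ---------------------------------------------------------------------------
# APACHE-II Acute Physiology Score
#
# Standard APACHE-II acute-physiology point bands.  Each entry is
# (edges, points): a value v scores points[searchsorted(edges, v, 'right')].
# GCS is absent from the data model and assumed normal (15 -> 0 points).

APS_BANDS: dict[str, tuple[list[float], list[int]]] = {
    "temperature": ([30, 32, 34, 36, 38.5, 39, 41], [4, 3, 2, 1, 0, 1, 3, 4]),
    "map":         ([50, 70, 110, 130, 160], [4, 2, 0, 2, 3, 4]),
    "heart_rate":  ([40, 55, 70, 110, 140, 180], [4, 3, 2, 0, 2, 3, 4]),
    "respiratory_rate": ([6, 10, 12, 25, 35, 50], [4, 2, 1, 0, 1, 3, 4]),
    "arterial_ph": ([7.15, 7.25, 7.33, 7.5, 7.6, 7.7], [4, 3, 2, 0, 1, 3, 4]),
    "sodium":      ([111, 120, 130, 150, 155, 160, 180], [4, 3, 2, 0, 1, 2, 3, 4]),
    "potassium":   ([2.5, 3.0, 3.5, 5.5, 6.0, 7.0], [4, 2, 1, 0, 1, 3, 4]),
    "creatinine":  ([0.6, 1.5, 2.0, 3.5], [2, 0, 2, 3, 4]),
    "hematocrit":  ([20, 30, 46, 50, 60], [4, 2, 0, 1, 2, 4]),
    "wbc":         ([1, 3, 15, 20, 40], [4, 2, 0, 1, 2, 4]),
    "pao2":        ([55, 61, 71], [4, 3, 1, 0]),      # used when FiO2 < 0.5
    "aado2":       ([200, 350, 500], [0, 2, 3, 4]),   # used when FiO2 >= 0.5
}

_APS_VITALS = {"temperature", "heart_rate", "respiratory_rate"}
_APS_LABS = {"arterial_ph", "sodium", "potassium", "creatinine",
             "hematocrit", "wbc", "map"}


def band_points(variable: str, values) -> np.ndarray:
    edges, pts = APS_BANDS[variable]
    return np.asarray(pts)[np.searchsorted(edges, np.asarray(values, float),
                                           side="right")]


def _oxygenation_points(day_grp: pd.DataFrame) -> int:
    """Day-level oxygenation points from PaO2/FiO2 (PaCO2 for the gradient).

    Readings are not co-timed in the source data, so the day's worst PaO2,
    highest FiO2 and lowest PaCO2 are combined; FiO2 absent -> room air 0.21.
    """
    vals = day_grp.groupby("analyte")["value"]
    agg = {a: (vals.get_group(a) if a in day_grp["analyte"].values else None)
           for a in ("pao2", "fio2", "paco2")}
    if agg["pao2"] is None:
        return 0
    pao2 = float(agg["pao2"].min())
    fio2 = float(agg["fio2"].max()) if agg["fio2"] is not None else 0.21
    if fio2 >= 0.5:
        paco2 = float(agg["paco2"].min()) if agg["paco2"] is not None else 40.0
        aado2 = fio2 * 713.0 - paco2 / 0.8 - pao2
        return int(band_points("aado2", [aado2])[0])
    return int(band_points("pao2", [pao2])[0])


def compute_aps(labs: pd.DataFrame, vitals: pd.DataFrame,
                sirs: pd.DataFrame) -> pd.DataFrame:
    """APACHE-II APS per SIRS-qualified encounter.

    Each of the qualification day (day 0) and the prior day (day -1) is
    scored separately using that day's most abnormal value per variable; the
    result is the larger daily total.  A missing variable scores 0 points.

    Returns (encounter_id, aps, day_used) with day_used in {0, -1}.
    """
    out = sirs[["encounter_id", "qualification_date"]].copy()
    if out.empty:
        out["aps"] = pd.Series(dtype=int)
        out["day_used"] = pd.Series(dtype=int)
        return out

    daily = {}  # (day_offset) -> DataFrame indexed by encounter_id with points total
    qual = out.set_index("encounter_id")["qualification_date"]

    def day_points(records: pd.DataFrame, value_col: str, var_col: str,
                   allowed: set[str]) -> pd.DataFrame:
        """Per (encounter, day-offset, variable) max APS points."""
        rec = records[records[var_col].isin(allowed)].copy()
        if rec.empty:
            return pd.DataFrame(columns=["encounter_id", "offset", "points"])
        rec["day"] = day_of(rec["datetime"])
        rec = rec.merge(qual.rename("qdate"), left_on="encounter_id",
                        right_index=True, how="inner")
        rec["offset"] = (rec["day"] - rec["qdate"]).dt.days
        rec = rec[rec["offset"].isin([0, -1])]
        if rec.empty:
            return pd.DataFrame(columns=["encounter_id", "offset", "points"])
        pts = np.zeros(len(rec), dtype=int)
        for var, idx in rec.groupby(var_col).groups.items():
            pos = rec.index.get_indexer(idx)
            pts[pos] = band_points(var, rec[value_col].to_numpy()[pos])
        rec["points"] = pts
        return (rec.groupby(["encounter_id", "offset", var_col])["points"]
                   .max().groupby(["encounter_id", "offset"]).sum()
                   .reset_index())

    parts = [day_points(vitals, "value", "vital", _APS_VITALS),
             day_points(labs, "value", "analyte", _APS_LABS)]

    # oxygenation handled jointly (PaO2 + FiO2 + PaCO2 on one day)
    ox = labs[labs["analyte"].isin(["pao2", "fio2", "paco2"])].copy()
    if not ox.empty:
        ox["day"] = day_of(ox["datetime"])
        ox = ox.merge(qual.rename("qdate"), left_on="encounter_id",
                      right_index=True, how="inner")
        ox["offset"] = (ox["day"] - ox["qdate"]).dt.days
        ox = ox[ox["offset"].isin([0, -1])]
        if not ox.empty:
            rows = [{"encounter_id": eid, "offset": off,
                     "points": _oxygenation_points(grp)}
                    for (eid, off), grp in ox.groupby(["encounter_id", "offset"])]
            parts.append(pd.DataFrame(rows))

    allpts = pd.concat([p for p in parts if not p.empty], ignore_index=True) \
        if any(not p.empty for p in parts) else pd.DataFrame(
            columns=["encounter_id", "offset", "points"])
    totals = (allpts.groupby(["encounter_id", "offset"])["points"].sum()
              .unstack(fill_value=0) if not allpts.empty else pd.DataFrame())
    for off in (0, -1):
        if off not in getattr(totals, "columns", []):
            totals[off] = 0
    totals = totals.reindex(out["encounter_id"]).fillna(0)
    day0 = totals[0].to_numpy()
    daym1 = totals[-1].to_numpy()
    out["aps"] = np.maximum(day0, daym1).astype(int)
    out["day_used"] = np.where(daym1 > day0, -1, 0)
    return out[["encounter_id", "aps", "day_used"]]


# ---------------------------------------------------------------------------
# Elixhauser comorbidities

def _normalize_icd9(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.replace(".", "", regex=False).str.upper()


def _match_prefix_set(codes: pd.Series, prefixes: list[str]) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=codes.index)
    pat = "|".join(sorted(prefixes, key=len, reverse=True))
    return codes.str.match(f"(?:{pat})")


def map_elixhauser(diagnoses: pd.DataFrame,
                   vocab: VocabularyConfig) -> pd.DataFrame:
    """Elixhauser comorbidity booleans per encounter (modified category set).

    ICD-9 codes are matched by prefix against the vocabulary's category map;
    codes 586 and 557.9 and the fluid/electrolyte category are excluded from
    that map for mutual exclusivity with measured outcomes.  Unknown codes
    are ignored.
    """
    cats = list(vocab.elixhauser)
    if diagnoses.empty:
        return pd.DataFrame(columns=["encounter_id"] + cats)
    codes = _normalize_icd9(diagnoses["icd9_code"])
    flags = pd.DataFrame({"encounter_id": diagnoses["encounter_id"]})
    for cat in cats:
        flags[cat] = _match_prefix_set(codes, vocab.elixhauser[cat])
    return flags.groupby("encounter_id", as_index=False).any()


# ---------------------------------------------------------------------------
# SOFA components (coagulation, liver, respiratory, cardiovascular)

def sofa_components(labs: pd.DataFrame, meds: pd.DataFrame,
                    sirs: pd.DataFrame, vocab: VocabularyConfig,
                    window_days: tuple[int, int] = (0, 3)) -> pd.DataFrame:
    """Standard SOFA subscores over the qualification-day window.

    Coagulation from the platelet nadir, liver from the bilirubin peak,
    respiratory from the worst day-level PaO2/FiO2 ratio, cardiovascular
    from vasopressor receipt (order-level data carry no doses, so any
    vasopressor scores 3) or MAP <70 mmHg.  Absent data scores 0.
    """
    out = sirs[["encounter_id", "qualification_date"]].copy()
    for c in ("cardio", "coagulation", "liver", "respiratory"):
        out[c] = 0
    if out.empty:
        return out.drop(columns="qualification_date")
    qual = out.set_index("encounter_id")["qualification_date"]
    lo, hi = window_days

    def in_window(df, time_col):
        d = df.merge(qual.rename("qdate"), left_on="encounter_id",
                     right_index=True, how="inner")
        off = (day_of(d[time_col]) - d["qdate"]).dt.days
        return d[(off >= lo) & (off <= hi)]

    out = out.set_index("encounter_id")
    if not labs.empty:
        w = in_window(labs, "datetime")
        plt_min = w[w["analyte"] == "platelets"].groupby("encounter_id")["value"].min()
        bili_max = w[w["analyte"] == "bilirubin"].groupby("encounter_id")["value"].max()
        coag = pd.cut(plt_min, [-np.inf, 20, 50, 100, 150, np.inf],
                      right=False, labels=[4, 3, 2, 1, 0]).astype(int)
        liver = pd.cut(bili_max, [-np.inf, 1.2, 2.0, 6.0, 12.0, np.inf],
                       right=False, labels=[0, 1, 2, 3, 4]).astype(int)
        out.loc[coag.index, "coagulation"] = coag
        out.loc[liver.index, "liver"] = liver

        # worst day-level PaO2/FiO2 (FiO2 missing -> room air 0.21)
        gas = w[w["analyte"].isin(["pao2", "fio2"])]
        if not gas.empty:
            g = gas.assign(day=day_of(gas["datetime"]))
            piv = g.pivot_table(index=["encounter_id", "day"], columns="analyte",
                                values="value", aggfunc={"value": ["min", "max"]})
            pao2 = piv.get(("min", "pao2"))
            if pao2 is not None:
                fio2 = piv.get(("max", "fio2"))
                fio2 = (fio2.fillna(0.21) if fio2 is not None
                        else pd.Series(0.21, index=piv.index))
                ratio = (pao2 / fio2).groupby("encounter_id").min().dropna()
                resp = pd.cut(ratio, [-np.inf, 100, 200, 300, 400, np.inf],
                              right=False, labels=[4, 3, 2, 1, 0]).astype(int)
                out.loc[resp.index, "respiratory"] = resp

        map_min = w[w["analyte"] == "map"].groupby("encounter_id")["value"].min()
        low_map = map_min[map_min < 70].index
        out.loc[low_map, "cardio"] = np.maximum(out.loc[low_map, "cardio"], 1)

    if not meds.empty:
        m = meds.copy()
        m["drug_class"] = [vocab.drug_class(d) for d in m["drug"]]
        vaso = in_window(m[m["drug_class"] == "vasopressor"], "datetime")
        ids = vaso["encounter_id"].unique()
        ids = [i for i in ids if i in out.index]
        out.loc[ids, "cardio"] = np.maximum(out.loc[ids, "cardio"], 3)

    return out.drop(columns="qualification_date").reset_index()


# ---------------------------------------------------------------------------
# KDIGO staging (serum creatinine only)

def kdigo_stage(labs: pd.DataFrame, sirs: pd.DataFrame,
                peak_window: tuple[int, int] = (0, 3)) -> pd.DataFrame:
    """Creatinine-only KDIGO AKI stage per SIRS-qualified encounter.

    Baseline is the lowest creatinine in the 7 days before qualification
    (days -7..-1).  The peak is searched over ``peak_window`` (default day 0
    through day +3).  Stage 1: peak >=1.5x baseline, or a rise >=0.3 mg/dL
    between readings <=48 h apart; stage 2: >=2.0x; stage 3: >=3.0x, or peak
    >=4.0 mg/dL alongside a qualifying stage-1 rise.  Encounters without a
    pre-qualification baseline are reported as stage 0 (not-AKI) with
    ``baseline_creatinine`` NaN.
    """
    out = sirs[["encounter_id", "qualification_date"]].copy()
    out["baseline_creatinine"] = np.nan
    out["peak_creatinine"] = np.nan
    out["stage"] = 0
    if out.empty or labs.empty:
        return out.drop(columns="qualification_date")
    cr = labs[labs["analyte"] == "creatinine"]
    if cr.empty:
        return out.drop(columns="qualification_date")
    out = out.set_index("encounter_id")
    qual = out["qualification_date"]
    cr = cr.merge(qual.rename("qdate"), left_on="encounter_id",
                  right_index=True, how="inner")
    cr = cr.assign(offset=(day_of(cr["datetime"]) - cr["qdate"]).dt.days)
    base = (cr[(cr["offset"] >= -7) & (cr["offset"] <= -1)]
            .groupby("encounter_id")["value"].min())
    lo, hi = peak_window
    inwin = cr[(cr["offset"] >= lo) & (cr["offset"] <= hi)]
    peak = inwin.groupby("encounter_id")["value"].max()

    # rise >=0.3 mg/dL between readings <=48 h apart, ending in the window
    rise48 = {}
    recent = cr[(cr["offset"] >= lo - 2) & (cr["offset"] <= hi)]
    for eid, grp in recent.groupby("encounter_id"):
        if len(grp) < 2:
            continue
        g = grp.sort_values("datetime")
        t = g["datetime"].to_numpy()
        v = g["value"].to_numpy()
        inw = (g["offset"].to_numpy() >= lo)
        hit = False
        for j in range(1, len(v)):
            if not inw[j]:
                continue
            back = (t[j] - t[:j]) <= np.timedelta64(48, "h")
            if back.any() and v[j] - v[:j][back].min() >= 0.3:
                hit = True
                break
        rise48[eid] = hit

    out.loc[base.index, "baseline_creatinine"] = base
    out.loc[peak.index, "peak_creatinine"] = peak
    both = base.index.intersection(peak.index)
    ratio = peak[both] / base[both]
    rise = pd.Series({e: rise48.get(e, False) for e in both})
    stage = pd.Series(0, index=both)
    s1 = (ratio >= 1.5) | rise
    stage[s1] = 1
    stage[ratio >= 2.0] = 2
    stage[(ratio >= 3.0) | ((peak[both] >= 4.0) & s1)] = 3
    out.loc[both, "stage"] = stage
    return out.drop(columns="qualification_date").reset_index()


def phenotype_bundle(bundle: EHRBundle, vocab: VocabularyConfig) -> dict[str, pd.DataFrame]:
    """Run all phenotyping stages on a bundle; returns keyed DataFrames."""
    sirs = detect_sirs(bundle.vitals, bundle.labs)
    return {
        "sirs": sirs,
        "aps": compute_aps(bundle.labs, bundle.vitals, sirs),
        "elixhauser": map_elixhauser(bundle.diagnoses, vocab),
        "sofa": sofa_components(bundle.labs, bundle.med_orders, sirs, vocab),
        "kdigo": kdigo_stage(bundle.labs, sirs),
    }
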