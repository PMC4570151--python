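"""Canonical tabular EHR data model, readers/writers and unit handling.

The pipeline's in-memory container is :class:`EHRBundle`, a set of linked
pandas DataFrames (patients, encounters, vitals, labs, fluid orders, med
orders, diagnoses, procedures, cultures) with declared schemas.  On disk each
table is one CSV with ISO-8601 datetimes; :func:`load_bundle` /
:func:`write_bundle` round-trip the content exactly.

Lab values are normalized to one canonical unit per analyte at load time so
every downstream threshold (e.g. potassium <3.5 mmol/L, hemoglobin drop
>20 g/L) is applied on a single scale.  Conversion factors are fixed
multiplicative constants registered in :data:`UNIT_REGISTRY`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import VocabularyConfig, VocabularyError

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input table does not match its declared schema."""


class UnitError(ValueError):
    """A lab unit is not registered for its analyte."""


# canonical unit and multiplicative conversion factors per analyte
UNIT_REGISTRY: dict[str, tuple[str, dict[str, float]]] = {
    "sodium": ("mmol/L", {"mmol/L": 1.0, "mEq/L": 1.0}),
    "potassium": ("mmol/L", {"mmol/L": 1.0, "mEq/L": 1.0}),
    "chloride": ("mmol/L", {"mmol/L": 1.0, "mEq/L": 1.0}),
    "bicarbonate": ("mmol/L", {"mmol/L": 1.0, "mEq/L": 1.0}),
    "magnesium": ("mmol/L", {"mmol/L": 1.0, "mEq/L": 0.5, "mg/dL": 0.4114}),
    "ionized_calcium": ("mmol/L", {"mmol/L": 1.0, "mEq/L": 0.5, "mg/dL": 0.2495}),
    "lactate": ("mmol/L", {"mmol/L": 1.0, "mg/dL": 1.0 / 9.01}),
    "creatinine": ("mg/dL", {"mg/dL": 1.0, "umol/L": 1.0 / 88.42}),
    "hemoglobin": ("g/L", {"g/L": 1.0, "g/dL": 10.0}),
    "platelets": ("1e9/L", {"1e9/L": 1.0, "1e3/uL": 1.0, "/mm3": 1e-3}),
    "wbc": ("1e9/L", {"1e9/L": 1.0, "1e3/uL": 1.0, "cells/mm3": 1e-3,
                      "cells/uL": 1e-3}),
    "arterial_ph": ("", {"": 1.0, "pH": 1.0}),
    "paco2": ("mmHg", {"mmHg": 1.0, "kPa": 7.50062}),
    "pao2": ("mmHg", {"mmHg": 1.0, "kPa": 7.50062}),
    "fio2": ("fraction", {"fraction": 1.0, "%": 0.01}),
    "map": ("mmHg", {"mmHg": 1.0}),
    "hematocrit": ("%", {"%": 1.0, "fraction": 100.0}),
    "troponin": ("ng/mL", {"ng/mL": 1.0, "ug/L": 1.0}),
    "bnp": ("pg/mL", {"pg/mL": 1.0}),
    "d_dimer": ("ng/mL", {"ng/mL": 1.0, "ug/mL": 1000.0, "mg/L": 1000.0}),
    "pt_inr": ("", {"": 1.0, "ratio": 1.0}),
    "bilirubin": ("mg/dL", {"mg/dL": 1.0, "umol/L": 1.0 / 17.1}),
}

FLUID_TYPES = ["calcium_free_balanced", "saline_09", "lactated_ringers",
               "saline_045", "colloid", "hypertonic_saline",
               "dextrose_containing", "other"]

VITAL_NAMES = ["heart_rate", "temperature", "respiratory_rate"]

# column -> dtype kind; 'dt' marks datetime columns parsed on load
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {"patient_id": "str", "age": "num", "gender": "str",
                 "race": "str"},
    "encounters": {"encounter_id": "str", "patient_id": "str",
                   "admit_datetime": "dt", "discharge_datetime": "dt",
                   "discharge_status": "str", "admission_source": "str",
                   "admission_type": "str", "payor": "str",
                   "bed_size": "str", "urban": "str", "teaching": "str",
                   "region": "str"},
    "vitals": {"encounter_id": "str", "vital": "str", "value": "num",
               "datetime": "dt"},
    "labs": {"encounter_id": "str", "analyte": "str", "value": "num",
             "unit": "str", "specimen": "str", "datetime": "dt"},
    "fluid_orders": {"encounter_id": "str", "fluid_type": "str",
                     "bag_volume_ml": "num", "datetime": "dt"},
    "med_orders": {"encounter_id": "str", "drug": "str", "route": "str",
                   "datetime": "dt"},
    "diagnoses": {"encounter_id": "str", "icd9_code": "str", "poa_flag": "str",
                  "sequence": "num"},
    "procedures": {"encounter_id": "str", "icd9_code": "str", "sequence": "num",
                   "datetime": "dt"},
    "cultures": {"encounter_id": "str", "specimen": "str", "result_date": "dt",
                 "positive": "str"},
}

DISCHARGE_STATUSES = {"home", "snf", "transfer", "hospice", "expired", "other"}


@dataclass
class EHRBundle:
    """Linked raw EHR tables; one DataFrame per table, schemas as declared."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    fluid_orders: pd.DataFrame
    med_orders: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    cultures: pd.DataFrame
    dropped_counts: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def table_names(self) -> list[str]:
        return list(TABLE_SCHEMAS)


def empty_table(name: str) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[name]
    data = {}
    for col, kind in schema.items():
        if kind == "dt":
            data[col] = pd.Series(dtype="datetime64[ns]")
        elif kind == "num":
            data[col] = pd.Series(dtype=float)
        else:
            data[col] = pd.Series(dtype=object)
    return pd.DataFrame(data)


def empty_bundle() -> EHRBundle:
    return EHRBundle(**{name: empty_table(name) for name in TABLE_SCHEMAS})


def normalize_unit(analyte: str, value: float, unit: str) -> tuple[float, str]:
    """Convert one lab value to its analyte's canonical unit.

    Returns ``(value_in_canonical_unit, canonical_unit)``.  Idempotent on
    records already in canonical units.  Raises :class:`UnitError` for an
    unregistered analyte/unit combination.
    """
    try:
        canonical, factors = UNIT_REGISTRY[analyte]
    except KeyError:
        raise UnitError(f"unregistered analyte: {analyte!r}") from None
    try:
        return value * factors[unit], canonical
    except KeyError:
        raise UnitError(f"unknown unit {unit!r} for analyte {analyte!r}") from None


def normalize_lab_table(labs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized canonical-unit conversion of a whole labs table."""
    if labs.empty:
        return labs.copy()
    labs = labs.copy()
    factors = np.ones(len(labs))
    canon = np.empty(len(labs), dtype=object)
    for (analyte, unit), idx in labs.groupby(["analyte", "unit"]).groups.items():
        _, new_unit = normalize_unit(analyte, 1.0, unit)
        f, _ = normalize_unit(analyte, 1.0, unit)
        pos = labs.index.get_indexer(idx)
        factors[pos] = f
        canon[pos] = new_unit
    labs["value"] = labs["value"].to_numpy() * factors
    labs["unit"] = canon
    return labs


def most_abnormal(values, threshold: float, direction: str) -> tuple[bool, float | None]:
    """Evaluate an abnormality rule over repeated readings of one analyte.

    ``direction`` is ``"below"`` (abnormal if value < threshold) or
    ``"above"`` (abnormal if value > threshold).  The most abnormal reading
    in the rule's direction is returned as the triggering value.  Zero
    readings means the value is assumed normal and the rule does not fire.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return False, None
    if direction == "below":
        extreme = float(arr.min())
        return extreme < threshold, extreme
    if direction == "above":
        extreme = float(arr.max())
        return extreme > threshold, extreme
    raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")


def _validate_columns(name: str, df: pd.DataFrame) -> None:
    missing = [c for c in TABLE_SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} missing required column(s): "
                          + ", ".join(missing))


def _read_table(name: str, path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    _validate_columns(name, df)
    for col, kind in TABLE_SCHEMAS[name].items():
        if kind == "dt":
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        elif kind == "num":
            df[col] = pd.to_numeric(df[col])
    return df


def load_bundle(paths: dict[str, str | Path], vocab: VocabularyConfig) -> EHRBundle:
    """Read, validate and link a bundle from per-table CSV paths.

    Patient rows missing any of patient_id/age/race/gender are dropped (with
    the count recorded in ``dropped_counts``), as are encounters that lose
    their patient, and child rows that lose their encounter.  Lab values are
    converted to canonical units.  Fluid orders carrying a free-text
    ``product`` column instead of ``fluid_type`` are resolved through the
    vocabulary; an unresolvable product raises :class:`VocabularyError`.
    """
    tables: dict[str, pd.DataFrame] = {}
    dropped: dict[str, int] = {}
    for name in TABLE_SCHEMAS:
        if name == "fluid_orders":
            df = pd.read_csv(paths[name], dtype=str, keep_default_na=False,
                             na_values=[""])
            if "fluid_type" not in df.columns and "product" in df.columns:
                df["fluid_type"] = [vocab.resolve_fluid_product(p)
                                    for p in df["product"]]
            _validate_columns(name, df)
            df["bag_volume_ml"] = pd.to_numeric(df["bag_volume_ml"])
            df["datetime"] = pd.to_datetime(df["datetime"], format="ISO8601")
            unknown = set(df["fluid_type"]) - set(vocab.fluid_chloride)
            if unknown:
                raise VocabularyError(f"unknown fluid type(s): {sorted(unknown)}")
            tables[name] = df
        else:
            tables[name] = _read_table(name, paths[name])

    pats = tables["patients"]
    keep = pats[["patient_id", "age", "gender", "race"]].notna().all(axis=1)
    keep &= pats["age"] >= 0
    dropped["patients"] = int((~keep).sum())
    tables["patients"] = pats[keep].reset_index(drop=True)

    encs = tables["encounters"]
    keep = encs["patient_id"].isin(tables["patients"]["patient_id"])
    keep &= encs["discharge_datetime"] >= encs["admit_datetime"]
    dropped["encounters"] = int((~keep).sum())
    tables["encounters"] = encs[keep].reset_index(drop=True)

    valid_enc = set(tables["encounters"]["encounter_id"])
    for name in ["vitals", "labs", "fluid_orders", "med_orders",
                 "diagnoses", "procedures", "cultures"]:
        df = tables[name]
        keep = df["encounter_id"].isin(valid_enc)
        dropped[name] = int((~keep).sum())
        tables[name] = df[keep].reset_index(drop=True)

    # dimensionless analytes (pH, INR) carry an empty unit string
    for col in ("unit", "specimen"):
        tables["labs"][col] = tables["labs"][col].fillna("")
    tables["labs"] = normalize_lab_table(tables["labs"])
    for name, n in dropped.items():
        if n:
            log.info("load_bundle: dropped %d row(s) from %s", n, name)
    return EHRBundle(**tables, dropped_counts=dropped)


def write_bundle(bundle: EHRBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every table as CSV under ``outdir``; returns per-table paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_SCHEMAS:
        df = bundle.table(name).copy()
        for col, kind in TABLE_SCHEMAS[name].items():
            if kind == "dt":
                df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def day_of(ts: pd.Series) -> pd.Series:
    """Calendar-day floor used by every 'same day' / 'within N days' rule."""
    return ts.dt.normalize()
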