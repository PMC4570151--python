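"""Vocabulary configuration: fluid catalog, drug classes, ICD-9 code sets.

The vocabulary bundles every site-editable mapping the pipeline needs:
which IV-fluid products map to which fluid type and chloride concentration,
which drug names belong to which therapeutic class, the ICD-9 code sets
behind administrative outcomes and exclusions, the Elixhauser comorbidity
prefix map, and the lab abnormality thresholds that the source data do not
define (troponin, D-dimer, INR).  Defaults ship as YAML next to this module;
pass a path to :func:`load_vocab` to override any of it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml


class VocabularyError(KeyError):
    """An order or code could not be resolved against the vocabulary."""


# Elixhauser modifications required for mutual exclusivity with outcomes:
# renal failure unspecified, and the peripheral-vascular code overlapping a
# GI administrative outcome.  Enforced on load regardless of config content.
_FORBIDDEN_ELIX_CODES = {"renal_failure": {"586"}, "peripheral_vascular": {"5579"}}
_FORBIDDEN_ELIX_CATEGORIES = {"fluid_electrolyte", "fluid_and_electrolyte_disorders"}


@dataclass
class VocabularyConfig:
    fluid_chloride: dict[str, float]
    fluid_products: dict[str, str]
    crystalloid_types: list[str]
    drug_classes: dict[str, list[str]]
    thresholds: dict[str, float]
    echo_order_names: list[str]
    admin_outcomes: dict[str, list[str]]
    procedure_sets: dict[str, list[str]]
    diagnosis_sets: dict[str, list[str]]
    elixhauser: dict[str, list[str]]
    _drug_to_class: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cat, forbidden in _FORBIDDEN_ELIX_CODES.items():
            if cat in self.elixhauser:
                self.elixhauser[cat] = [c for c in self.elixhauser[cat]
                                        if c not in forbidden]
        for cat in _FORBIDDEN_ELIX_CATEGORIES:
            self.elixhauser.pop(cat, None)
        self._drug_to_class = {
            drug.lower(): cls
            for cls, drugs in self.drug_classes.items()
            for drug in drugs
        }

    def chloride_mmol_per_l(self, fluid_type: str) -> float:
        try:
            return self.fluid_chloride[fluid_type]
        except KeyError:
            raise VocabularyError(f"unknown fluid type: {fluid_type!r}") from None

    def resolve_fluid_product(self, product_name: str) -> str:
        """Map a free-text product name to a fluid type (substring match)."""
        name = product_name.lower()
        for key, ftype in self.fluid_products.items():
            if key in name:
                return ftype
        raise VocabularyError(f"unresolvable fluid product: {product_name!r}")

    def drug_class(self, drug: str) -> str | None:
        return self._drug_to_class.get(drug.lower())


def _normalize_codes(codes: list) -> list[str]:
    return [str(c).replace(".", "").upper() for c in codes]


def load_vocab(path: str | None = None) -> VocabularyConfig:
    """Load the vocabulary from ``path``, or the packaged defaults."""
    if path is None:
        ref = importlib.resources.files("sirsfluids.data") / "default_vocab.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    fluids = raw["fluids"]
    return VocabularyConfig(
        fluid_chloride={k: float(v) for k, v in fluids["catalog"].items()},
        fluid_products=dict(fluids.get("products", {})),
        crystalloid_types=list(fluids["crystalloid_types"]),
        drug_classes={k: list(v) for k, v in raw["drug_classes"].items()},
        thresholds={k: float(v) for k, v in raw["thresholds"].items()},
        echo_order_names=list(raw.get("echo_order_names", [])),
        admin_outcomes={k: _normalize_codes(v)
                        for k, v in raw["admin_outcomes"].items()},
        procedure_sets={k: _normalize_codes(v)
                        for k, v in raw["procedure_sets"].items()},
        diagnosis_sets={k: _normalize_codes(v)
                        for k, v in raw["diagnosis_sets"].items()},
        elixhauser={k: _normalize_codes(v) for k, v in raw["elixhauser"].items()},
    )
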