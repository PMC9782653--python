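"""Substance-dossier data model and JSON/CSV serialization.

A dossier collects everything a first-tier assessor asserts about one
candidate additive: identity, hazard flags (sensitization, genotoxicity,
phenolic-acetate moiety, allergen sourcing, …), TTC routing attributes
(Cramer class, OASIS mode of action, exclusion category) and zero or more
point-of-departure (POD) records from the toxicological literature. Hazard
flags are *user-asserted* inputs — this module does no chemistry and no
database lookups; flags typically come from Safety Data Sheets or regulatory
classifications.

JSON is the canonical nested form. The CSV dialect is one row per POD with
the dossier-level columns repeated on every row (one dossier per file), so
spreadsheets remain usable for data entry.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from pathlib import Path
from typing import Any, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_serializer,
    field_validator,
    model_validator,
)

from .errors import DossierFormatError, DossierValidationError

logger = logging.getLogger(__name__)

# Hazard flags whose absence from an input file is logged as "not asserted"
# rather than silently treated as a clean bill of health.
_HAZARD_FLAGS = (
    "is_respiratory_sensitizer",
    "genotoxicity_alert",
    "is_organophosphate_or_carbamate",
    "is_phenolic_acetate",
    "is_supplement_vitamin_or_hphc",
    "is_big8_allergen_source",
)


class PodUnits(str, enum.Enum):
    MG_PER_KG_BW_PER_DAY = "mg_per_kg_bw_per_day"
    MG_PER_M3 = "mg_per_m3"
    MG_PER_DAY = "mg_per_day"


class PodType(str, enum.Enum):
    """Acceptable point-of-departure types.

    LD50/LC50 are deliberately unrepresentable: lethality benchmarks are not
    valid PODs for deriving a safety limit.
    """

    NOAEL = "NOAEL"
    NOAEC = "NOAEC"
    LOAEL = "LOAEL"
    LOAEC = "LOAEC"
    REGULATORY_LIMIT = "regulatory_limit"


class RegulatoryWindow(str, enum.Enum):
    STEL_15MIN = "stel_15min"
    TWA_8H = "twa_8h"
    CONTINUOUS_24H = "continuous_24h"
    NOT_APPLICABLE = "not_applicable"


class Route(str, enum.Enum):
    ORAL = "oral"
    INHALATION = "inhalation"
    DERMAL = "dermal"


class Species(str, enum.Enum):
    HUMAN = "human"
    ANIMAL = "animal"


class SensitiveSubpopulation(str, enum.Enum):
    """Whether the key study tested a sensitive subpopulation (drives UF2 relief)."""

    NONE = "none"
    MODERATE = "moderate"
    STRONG = "strong"


class DurationClass(str, enum.Enum):
    SUBACUTE = "subacute"            # 14-90 days
    SUBCHRONIC = "subchronic"        # 90 days - 1 year
    CHRONIC = "chronic"              # >= 1 year
    CLINICAL_OR_LIFETIME = "clinical_or_lifetime"


class EndpointScope(str, enum.Enum):
    SYSTEMIC = "systemic"
    LOCAL_RESPIRATORY = "local_respiratory"


class CarcinogenClassification(str, enum.Enum):
    NONE = "none"
    LISTED = "listed"


class TtcExclusionCategory(str, enum.Enum):
    """Structural categories for which the TTC approach cannot be used at all."""

    NONE = "none"
    INORGANIC = "inorganic"
    RADIOACTIVE = "radioactive"
    NANOPARTICLE = "nanoparticle"
    BIOACCUMULATIVE = "bioaccumulative"
    PROTEIN = "protein"
    POLYMER = "polymer"
    AFLATOXIN_LIKE = "aflatoxin_like"
    STEROID = "steroid"
    POLYHALOGENATED_DIOXIN_LIKE = "polyhalogenated_dioxin_like"
    POLYCYCLIC_AMINE = "polycyclic_amine"
    HYDRAZINE_LIKE = "hydrazine_like"
    NITROSO = "nitroso"
    ALPHA_NITRO_FURYL = "alpha_nitro_furyl"


class CramerClass(str, enum.Enum):
    ONE = "1"
    TWO = "2"
    THREE = "3"
    UNKNOWN = "unknown"


class OasisMoa(str, enum.Enum):
    BASE_SURFACE_NARCOTIC = "base_surface_narcotic"
    REACTIVE = "reactive"
    UNKNOWN = "unknown"


class EvidenceTier(str, enum.Enum):
    """Study-relevance weighting bucket; metadata only, never used in arithmetic."""

    VAPORIZATION_CANNABIS = "vaporization_cannabis"
    VAPORIZATION_OTHER = "vaporization_other"
    INHALATION_GUIDELINE = "inhalation_guideline"
    INHALATION_OTHER = "inhalation_other"
    OTHER_ROUTE_GUIDELINE = "other_route_guideline"
    OTHER_ROUTE_OTHER = "other_route_other"


class ExposureDurationTier(str, enum.Enum):
    """Intended consumer exposure duration; selects the genotoxic TTC tier."""

    LT_1_MONTH = "lt_1_month"
    MONTHS_1_TO_12 = "1_to_12_months"
    YEARS_1_TO_10 = "1_to_10_years"
    GT_10_YEARS_LIFETIME = "gt_10_years_lifetime"


class PodRecord(BaseModel):
    """One point of departure (NOAEL/NOAEC/LOAEL/LOAEC or regulatory limit).

    ``hours_per_day`` / ``days_per_week`` describe the *study* dosing schedule
    and drive the continuous-exposure adjustment; ``test_article_purity``
    scales the POD down when the tested material was impure.
    """

    model_config = ConfigDict(extra="forbid")

    value: float = Field(gt=0)
    units: PodUnits
    pod_type: PodType
    regulatory_window: RegulatoryWindow = RegulatoryWindow.NOT_APPLICABLE
    route: Route
    species: Species
    tested_sensitive_subpopulation: SensitiveSubpopulation = SensitiveSubpopulation.NONE
    duration_class: DurationClass
    hours_per_day: float = Field(default=24.0, gt=0, le=24)
    days_per_week: float = Field(default=7.0, gt=0, le=7)
    test_article_purity: float = Field(default=1.0, gt=0, le=1)
    endpoint_scope: EndpointScope = EndpointScope.SYSTEMIC
    # Measured oral:inhalation absorption ratio; when present it replaces the
    # default toxicokinetic component of the route-extrapolation factor.
    oral_to_inhalation_absorption_ratio: Optional[float] = Field(default=None, gt=0)
    uf_categories_already_addressed: set[int] = Field(default_factory=set)

    @field_validator("uf_categories_already_addressed")
    @classmethod
    def _uf_categories_in_range(cls, v: set[int]) -> set[int]:
        bad = sorted(c for c in v if c not in {1, 2, 3, 4, 5, 6})
        if bad:
            raise ValueError(f"uf_categories_already_addressed must be within 1..6, got {bad}")
        return v

    @field_serializer("uf_categories_already_addressed")
    def _serialize_uf_categories(self, v: set[int]) -> list[int]:
        return sorted(v)

    @model_validator(mode="after")
    def _check_regulatory_consistency(self) -> "PodRecord":
        if self.pod_type is not PodType.REGULATORY_LIMIT:
            if self.regulatory_window is not RegulatoryWindow.NOT_APPLICABLE:
                raise ValueError(
                    "regulatory_window must be not_applicable unless pod_type is regulatory_limit"
                )
        else:
            if self.units not in (PodUnits.MG_PER_M3, PodUnits.MG_PER_DAY):
                raise ValueError(
                    "regulatory_limit PODs must carry units mg_per_m3 or mg_per_day"
                )
        return self


class SubstanceDossier(BaseModel):
    """Everything asserted about one candidate additive.

    Booleans default to False, which for hazard flags means "not asserted";
    loaders log which hazard flags were absent from the input so the audit
    trail shows what was affirmatively claimed versus merely unstated.
    """

    model_config = ConfigDict(extra="forbid")

    name: str = Field(min_length=1)
    cas_number: Optional[str] = None
    purity_fraction: float = Field(default=1.0, gt=0, le=1)
    is_respiratory_sensitizer: bool = False
    native_to_cannabis: bool = False
    plant_ratio_to_thc: Optional[float] = Field(default=None, ge=0)
    genotoxicity_alert: bool = False
    carcinogen_classification: CarcinogenClassification = CarcinogenClassification.NONE
    carcinogen_source_note: Optional[str] = None
    is_organophosphate_or_carbamate: bool = False
    is_phenolic_acetate: bool = False
    is_supplement_vitamin_or_hphc: bool = False
    is_big8_allergen_source: bool = False
    gras_or_food_use: bool = False
    ttc_exclusion_category: TtcExclusionCategory = TtcExclusionCategory.NONE
    cramer_class: CramerClass = CramerClass.UNKNOWN
    oasis_moa: OasisMoa = OasisMoa.UNKNOWN
    developmental_data_available: bool = False
    # Tri-state: None = not assessed (conservative UF6=10 applies),
    # True = structure suggests developmental potential (UF6=10),
    # False = structure not suggestive (UF6=3 allowed).
    developmental_structural_alert: Optional[bool] = None
    evidence_tier: EvidenceTier = EvidenceTier.OTHER_ROUTE_OTHER
    pods: list[PodRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _plant_ratio_requires_native(self) -> "SubstanceDossier":
        if not self.native_to_cannabis and self.plant_ratio_to_thc is not None:
            raise ValueError(
                "plant_ratio_to_thc may only be given when native_to_cannabis is true"
            )
        return self


class ProductContext(BaseModel):
    """Properties of the finished product the additive would go into."""

    model_config = ConfigDict(extra="forbid")

    product_thc_concentration: float = Field(default=850.0, ge=0, le=1000)
    age_gated: bool = False
    intended_exposure_duration: ExposureDurationTier = ExposureDurationTier.GT_10_YEARS_LIFETIME


def dossier_json_schema() -> dict[str, Any]:
    """JSON schema for the canonical nested dossier form."""
    return SubstanceDossier.model_json_schema()


# --------------------------------------------------------------------------
# serialization helpers

_DOSSIER_SCALAR_FIELDS = [f for f in SubstanceDossier.model_fields if f != "pods"]
_POD_FIELDS = list(PodRecord.model_fields)

_CSV_HEADER = _DOSSIER_SCALAR_FIELDS + [f"pod_{f}" for f in _POD_FIELDS]


def _to_cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, (set, frozenset)):
        return ";".join(str(x) for x in sorted(value))
    return str(value)


def _validate(data: dict[str, Any]) -> SubstanceDossier:
    try:
        dossier = SubstanceDossier.model_validate(data)
    except ValidationError as exc:
        violations = [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise DossierValidationError(violations) from exc
    missing = [f for f in _HAZARD_FLAGS if f not in data]
    if missing:
        logger.info(
            "dossier %r: hazard flags not asserted in input (treated as false): %s",
            dossier.name,
            ", ".join(missing),
        )
    return dossier


def load_dossier(path: str | Path, format: Optional[str] = None) -> SubstanceDossier:
    """Load and validate a dossier from JSON or CSV.

    ``format`` defaults to the file suffix. Parse failures raise
    :class:`DossierFormatError`; invariant violations raise
    :class:`DossierValidationError` listing every violated invariant.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise DossierFormatError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(data, dict):
            raise DossierFormatError(f"{path}: top level must be a JSON object")
        return _validate(data)
    if fmt == "csv":
        return _load_dossier_csv(path)
    raise DossierFormatError(f"unsupported dossier format {fmt!r} (expected json or csv)")


_BOOL_FIELDS = {
    name
    for model in (SubstanceDossier, PodRecord)
    for name, info in model.model_fields.items()
    if info.annotation in (bool, Optional[bool])
}


def _parse_cell(field: str, raw: str) -> Any:
    raw = raw.strip()
    if field in _BOOL_FIELDS:
        if raw.lower() in ("true", "false"):
            return raw.lower() == "true"
        raise DossierFormatError(f"field {field}: expected true/false, got {raw!r}")
    if field == "uf_categories_already_addressed":
        try:
            return {int(x) for x in raw.split(";") if x.strip()}
        except ValueError as exc:
            raise DossierFormatError(
                f"field uf_categories_already_addressed: cannot parse {raw!r}"
            ) from exc
    return raw


def _load_dossier_csv(path: Path) -> SubstanceDossier:
    with open(path, newline="", encoding="utf-8") as fh:
        try:
            rows = list(csv.DictReader(fh))
        except csv.Error as exc:
            raise DossierFormatError(f"{path}: invalid CSV: {exc}") from exc
    if not rows:
        raise DossierFormatError(f"{path}: CSV contains no data rows")
    data: dict[str, Any] = {}
    first = rows[0]
    for field in _DOSSIER_SCALAR_FIELDS:
        raw = first.get(field)
        if raw is not None and raw.strip() != "":
            data[field] = _parse_cell(field, raw)
    # every row must describe the same dossier (one dossier per file)
    for i, row in enumerate(rows[1:], start=2):
        for field in _DOSSIER_SCALAR_FIELDS:
            a = (first.get(field) or "").strip()
            b = (row.get(field) or "").strip()
            if a != b:
                raise DossierFormatError(
                    f"{path}: row {i} disagrees with row 1 on dossier field {field!r} "
                    f"({b!r} vs {a!r}); a CSV file holds exactly one dossier"
                )
    pods = []
    for row in rows:
        pod_cells = {
            f: _parse_cell(f, row[f"pod_{f}"])
            for f in _POD_FIELDS
            if row.get(f"pod_{f}") is not None and row[f"pod_{f}"].strip() != ""
        }
        if pod_cells:
            pods.append(pod_cells)
    if pods:
        data["pods"] = pods
    return _validate(data)


def write_dossier(dossier: SubstanceDossier, path: str | Path, format: Optional[str] = None) -> None:
    """Write a dossier to JSON (canonical) or CSV (one row per POD).

    Round-trip identity holds: ``load_dossier(p) == dossier`` for either format.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        path.write_text(
            json.dumps(dossier.model_dump(mode="json"), indent=2) + "\n", encoding="utf-8"
        )
        return
    if fmt == "csv":
        scalar = {f: _to_cell(getattr(dossier, f)) for f in _DOSSIER_SCALAR_FIELDS}
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_HEADER)
            writer.writeheader()
            if dossier.pods:
                for pod in dossier.pods:
                    row = dict(scalar)
                    row.update({f"pod_{f}": _to_cell(getattr(pod, f)) for f in _POD_FIELDS})
                    writer.writerow(row)
            else:
                writer.writerow(scalar)
        return
    raise DossierFormatError(f"unsupported dossier format {fmt!r} (expected json or csv)")
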