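"""Threshold-of-toxicological-concern (TTC) decision tree.

For data-poor additives with no usable POD, generic µg/day exposure limits
are assigned by a five-question tree, evaluated strictly in order:

  Q1  Is the substance in a category TTC cannot cover (inorganics,
      radioactives, nanoparticles, bioaccumulatives, proteins, polymers,
      aflatoxin-like, steroids, dioxin-like polyhalogenates, polycyclic
      amines, hydrazine-like, nitroso, α-nitro-furyl)? → not applicable.
  Q2  Organophosphate or carbamate? → 18 µg/day.
  Q3  Genotoxicity alert? → duration-tiered: 1.5 (>10 y–lifetime),
      10 (1–10 y), 20 (1–12 months), 120 (<1 month) µg/day.
  Q4  Cannabis-native or GRAS/food-use? → Cramer class 1: 865 µg/day;
      class 2 or 3: 145 µg/day (food-relevant inhalation TTC).
  Q5  Otherwise → OASIS acute-aquatic mode of action: base-surface
      narcotics 22.39 µg/day; reactive 4.286 µg/day (broad-chemical TTC).

Cramer class and OASIS MOA are dossier inputs classified externally (e.g.
ToxTree, OECD QSAR Toolbox); this module does no structural chemistry.
The limits table ships as a versioned JSON data file so it can be audited
or overridden.
"""

from __future__ import annotations

import enum
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, model_validator

from .dossier_io import (
    CarcinogenClassification,
    CramerClass,
    OasisMoa,
    ProductContext,
    SubstanceDossier,
    TtcExclusionCategory,
)
from .errors import ClassificationRequiredError

logger = logging.getLogger(__name__)


class TtcCategory(str, enum.Enum):
    NOT_APPLICABLE = "not_applicable"
    ORGANOPHOSPHATE_CARBAMATE = "organophosphate_carbamate"
    GENOTOXIC_TIERED = "genotoxic_tiered"
    CRAMER_CLASS_1 = "cramer_class_1"
    CRAMER_CLASS_2_OR_3 = "cramer_class_2_or_3"
    OASIS_BASE_SURFACE_NARCOTIC = "oasis_base_surface_narcotic"
    OASIS_REACTIVE = "oasis_reactive"


class TtcResult(BaseModel):
    applicable: bool
    category: TtcCategory
    limit_ug_per_day: Optional[float] = None
    rationale: list[str] = []

    @model_validator(mode="after")
    def _invariants(self) -> "TtcResult":
        na = self.category is TtcCategory.NOT_APPLICABLE
        if self.applicable == na:
            raise ValueError("applicable=false iff category=not_applicable")
        if (self.limit_ug_per_day is None) != na:
            raise ValueError("limit present iff applicable")
        if self.limit_ug_per_day is not None and self.limit_ug_per_day <= 0:
            raise ValueError("limit must be positive")
        return self


def load_ttc_limits(path: Optional[str | Path] = None) -> dict[str, Any]:
    """Load the versioned TTC limits table (package default or an override file)."""
    if path is not None:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    return json.loads(
        resources.files("cannrisk.data").joinpath("ttc_limits.json").read_text(encoding="utf-8")
    )


def route_ttc(
    dossier: SubstanceDossier,
    context: ProductContext,
    limits_table: Optional[dict[str, Any]] = None,
    conservative: bool = False,
) -> TtcResult:
    """Walk the decision tree in printed order and return the µg/day limit.

    ``conservative=True`` instead returns the minimum across every branch
    (Q2–Q5) whose predicate holds, mirroring the advice to run multiple
    models and keep the more conservative value.
    """
    table = (limits_table or load_ttc_limits())["limits_ug_per_day"]
    rationale: list[str] = []

    # Q1 — structural exclusion from the TTC approach
    if dossier.ttc_exclusion_category is not TtcExclusionCategory.NONE:
        rationale.append(
            f"Q1: substance is in TTC exclusion category "
            f"'{dossier.ttc_exclusion_category.value}' → TTC cannot be used"
        )
        return TtcResult(
            applicable=False, category=TtcCategory.NOT_APPLICABLE, rationale=rationale
        )
    rationale.append("Q1: no TTC exclusion category → proceed")

    if (
        dossier.carcinogen_classification is CarcinogenClassification.LISTED
        and not dossier.genotoxicity_alert
    ):
        msg = (
            "carcinogen listing without a genotoxicity alert: the genotoxic tier is "
            "not triggered; expert review recommended"
        )
        logger.warning("dossier %r: %s", dossier.name, msg)
        rationale.append(f"note: {msg}")

    # Matched branches in question order. In the printed tree the first match
    # answers and later questions are never reached; conservative mode keeps
    # collecting and takes the minimum.
    branches: list[tuple[TtcCategory, float, str]] = []

    def finalize() -> TtcResult:
        if conservative and len(branches) > 1:
            category, limit, why = min(branches, key=lambda b: b[1])
            rationale.append(
                "conservative mode: minimum over branches "
                + ", ".join(f"{b[0].value}={b[1]:g}" for b in branches)
            )
        else:
            category, limit, why = branches[0]
        rationale.append(f"{why} → {limit:g} µg/day")
        return TtcResult(
            applicable=True, category=category, limit_ug_per_day=limit, rationale=rationale
        )

    # Q2 — organophosphates / carbamates
    if dossier.is_organophosphate_or_carbamate:
        branches.append(
            (
                TtcCategory.ORGANOPHOSPHATE_CARBAMATE,
                float(table["organophosphate_carbamate"]),
                "Q2: organophosphate or carbamate",
            )
        )
        if dossier.genotoxicity_alert:
            msg = (
                "organophosphate/carbamate also carries a genotoxicity alert; the "
                "printed order assigns the organophosphate tier — expert review advised"
            )
            logger.warning("dossier %r: %s", dossier.name, msg)
            rationale.append(f"note: {msg}")
        if not conservative:
            return finalize()
    rationale.append("Q2: not an organophosphate/carbamate" if not branches else "Q2: matched")

    # Q3 — genotoxicity, tiered by intended exposure duration
    if dossier.genotoxicity_alert:
        tier = context.intended_exposure_duration.value
        branches.append(
            (
                TtcCategory.GENOTOXIC_TIERED,
                float(table["genotoxic"][tier]),
                f"Q3: genotoxicity alert, intended exposure '{tier}'",
            )
        )
        if not conservative:
            return finalize()

    # Q4 — cannabis-native or GRAS/food-use → Cramer class
    if dossier.native_to_cannabis or dossier.gras_or_food_use:
        if dossier.cramer_class is CramerClass.UNKNOWN:
            if not branches:
                raise ClassificationRequiredError(
                    "TTC routing reached Q4 but cramer_class is unknown: classify the "
                    "substance with ToxTree or the OECD QSAR Toolbox and record the "
                    "Cramer class in the dossier"
                )
            rationale.append("Q4: cramer_class unknown, skipped (earlier branch matched)")
        else:
            if dossier.cramer_class is CramerClass.ONE:
                branches.append(
                    (
                        TtcCategory.CRAMER_CLASS_1,
                        float(table["cramer_class_1"]),
                        "Q4: cannabis-native/GRAS substance, Cramer class 1",
                    )
                )
            else:
                branches.append(
                    (
                        TtcCategory.CRAMER_CLASS_2_OR_3,
                        float(table["cramer_class_2_or_3"]),
                        f"Q4: cannabis-native/GRAS substance, Cramer class "
                        f"{dossier.cramer_class.value}",
                    )
                )
            if not conservative:
                return finalize()
    else:
        # Q5 — fallback on broad-chemical MOA limits
        if dossier.oasis_moa is OasisMoa.UNKNOWN:
            if not branches:
                raise ClassificationRequiredError(
                    "TTC routing reached Q5 but oasis_moa is unknown: profile the acute "
                    "aquatic mode of action with the OECD QSAR Toolbox (OASIS) and record "
                    "it in the dossier"
                )
            rationale.append("Q5: oasis_moa unknown, skipped (earlier branch matched)")
        else:
            if dossier.oasis_moa is OasisMoa.BASE_SURFACE_NARCOTIC:
                branches.append(
                    (
                        TtcCategory.OASIS_BASE_SURFACE_NARCOTIC,
                        float(table["oasis_base_surface_narcotic"]),
                        "Q5: non-food substance, OASIS base/surface narcotic",
                    )
                )
            else:
                branches.append(
                    (
                        TtcCategory.OASIS_REACTIVE,
                        float(table["oasis_reactive"]),
                        "Q5: non-food substance, OASIS reactive",
                    )
                )
            if not conservative:
                return finalize()

    return finalize()
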