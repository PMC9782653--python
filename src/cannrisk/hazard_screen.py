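"""Categorical exclusion rules applied before any dose-response arithmetic.

Certain classes of additive are screened out of a first-tier assessment
outright: respiratory sensitizers not native to the cannabis plant, major
food-allergen sources, phenolic acetates (the vitamin E acetate / EVALI
lesson), and supplements/vitamins/HPHCs. Genotoxicity or a carcinogen
listing does not exclude by default — it routes the substance to the
genotoxic TTC tier — but a strict mode turns it into an exclusion.

Sensitizers that *are* native to cannabis are not excluded; instead their
concentration is capped at the level the plant itself delivers relative to
THC (``plant_ratio_to_thc × product THC concentration``).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .dossier_io import CarcinogenClassification, ProductContext, SubstanceDossier
from .errors import MissingPlantRatioError

# Stable rule identifiers emitted in reports and logs.
RULE_NON_NATIVE_SENSITIZER = "RULE_NON_NATIVE_SENSITIZER"
RULE_NATIVE_SENSITIZER_CAP = "RULE_NATIVE_SENSITIZER_CAP"
RULE_BIG8_ALLERGEN = "RULE_BIG8_ALLERGEN"
RULE_PHENOLIC_ACETATE = "RULE_PHENOLIC_ACETATE"
RULE_SUPPLEMENT_VITAMIN_HPHC = "RULE_SUPPLEMENT_VITAMIN_HPHC"
RULE_GENOTOX_TTC_ROUTE = "RULE_GENOTOX_TTC_ROUTE"
RULE_GENOTOX_STRICT_EXCLUSION = "RULE_GENOTOX_STRICT_EXCLUSION"


class ScreenVerdict(str, enum.Enum):
    PASS = "pass"
    EXCLUDE = "exclude"
    CONDITIONAL_CAP = "conditional_cap"


class ScreenReason(BaseModel):
    rule: str
    text: str


class ScreenResult(BaseModel):
    verdict: ScreenVerdict
    reasons: list[ScreenReason] = []
    # mg additive per g concentrate; present iff verdict is conditional_cap
    cap_concentration_mg_per_g: Optional[float] = None

    @model_validator(mode="after")
    def _invariants(self) -> "ScreenResult":
        if self.verdict is ScreenVerdict.EXCLUDE and not self.reasons:
            raise ValueError("exclusion requires at least one reason")
        if (self.cap_concentration_mg_per_g is not None) != (
            self.verdict is ScreenVerdict.CONDITIONAL_CAP
        ):
            raise ValueError("cap_concentration present iff verdict is conditional_cap")
        if self.cap_concentration_mg_per_g is not None and self.cap_concentration_mg_per_g < 0:
            raise ValueError("cap_concentration must be >= 0")
        return self


def native_sensitizer_cap(
    plant_ratio_to_thc: Optional[float], product_thc_concentration: float
) -> float:
    """Concentration cap (mg/g) for a cannabis-native respiratory sensitizer.

    The additive must stay at or below the level the plant itself delivers
    relative to THC: ``plant_ratio_to_thc × product_thc_concentration``.
    """
    if plant_ratio_to_thc is None:
        raise MissingPlantRatioError(
            "no plant_ratio_to_thc in dossier: supply the additive's natural "
            "concentration in cannabis inflorescence relative to THC to cap a "
            "native respiratory sensitizer"
        )
    if plant_ratio_to_thc < 0 or product_thc_concentration < 0:
        raise ValueError("plant ratio and THC concentration must be non-negative")
    return plant_ratio_to_thc * product_thc_concentration


def screen_substance(
    dossier: SubstanceDossier,
    context: ProductContext,
    strict_genotoxicity: bool = False,
) -> ScreenResult:
    """Apply every exclusion rule; all triggered rules are listed (no short-circuit)."""
    reasons: list[ScreenReason] = []
    exclude = False
    cap: Optional[float] = None

    if dossier.is_respiratory_sensitizer:
        if not dossier.native_to_cannabis:
            exclude = True
            reasons.append(
                ScreenReason(
                    rule=RULE_NON_NATIVE_SENSITIZER,
                    text="respiratory sensitizer not naturally occurring in cannabis: "
                    "entirely avoided (effect severity, extremely low safety limits)",
                )
            )
        else:
            cap = native_sensitizer_cap(
                dossier.plant_ratio_to_thc, context.product_thc_concentration
            )
            reasons.append(
                ScreenReason(
                    rule=RULE_NATIVE_SENSITIZER_CAP,
                    text=f"cannabis-native respiratory sensitizer: concentration capped at "
                    f"the plant-relative level ({cap:.6g} mg/g at "
                    f"{context.product_thc_concentration:g} mg/g THC)",
                )
            )

    if dossier.is_big8_allergen_source:
        exclude = True
        reasons.append(
            ScreenReason(
                rule=RULE_BIG8_ALLERGEN,
                text="sourced from or contaminated with a Big-8 food allergen: avoided",
            )
        )

    if dossier.is_phenolic_acetate:
        exclude = True
        reasons.append(
            ScreenReason(
                rule=RULE_PHENOLIC_ACETATE,
                text="contains a phenolic acetate moiety (vitamin E acetate class, "
                "EVALI-implicated ketene precursor): avoided",
            )
        )

    if dossier.is_supplement_vitamin_or_hphc:
        exclude = True
        reasons.append(
            ScreenReason(
                rule=RULE_SUPPLEMENT_VITAMIN_HPHC,
                text="herbal/dietary supplement, vitamin, mineral or listed HPHC: avoided",
            )
        )

    genotoxic = (
        dossier.genotoxicity_alert
        or dossier.carcinogen_classification is CarcinogenClassification.LISTED
    )
    if genotoxic:
        if strict_genotoxicity:
            exclude = True
            reasons.append(
                ScreenReason(
                    rule=RULE_GENOTOX_STRICT_EXCLUSION,
                    text="genotoxic/carcinogenic substance excluded (strict mode)",
                )
            )
        else:
            reasons.append(
                ScreenReason(
                    rule=RULE_GENOTOX_TTC_ROUTE,
                    text="genotoxicity alert or carcinogen listing: route to genotoxic "
                    "TTC tier (not an automatic exclusion)",
                )
            )

    if exclude:
        return ScreenResult(verdict=ScreenVerdict.EXCLUDE, reasons=reasons)
    if cap is not None:
        return ScreenResult(
            verdict=ScreenVerdict.CONDITIONAL_CAP,
            reasons=reasons,
            cap_concentration_mg_per_g=cap,
        )
    return ScreenResult(verdict=ScreenVerdict.PASS, reasons=reasons)
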