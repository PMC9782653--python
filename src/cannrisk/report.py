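"""Risk characterization and full assessment-report assembly.

The comparison at the heart of the framework: if the estimated daily
exposure to the additive is at or below the governing safety limit (POD- or
TTC-derived, in mg/day), the first-tier toxicological risk is low;
otherwise the additive must be removed, reduced in concentration, or taken
to a higher-tier assessment. The maximum allowable concentration is the
back-calculation

    max allowable concentration (% w/w) = limit (mg/day) / consumption (mg/day) × 100.

``run_assessment`` orchestrates the whole pipeline — screen → limit
derivation (POD path or TTC route) → exposure → characterization →
back-calculation — and emits a self-contained, audit-trailed report.
"""

from __future__ import annotations

import enum
import warnings
from typing import Optional

from pydantic import BaseModel, Field

from . import __version__ as _package_version
from .audit import AuditLog
from .dossier_io import PodType, ProductContext, SubstanceDossier
from .errors import (
    ClassificationRequiredError,
    InsufficientDataError,
    MissingPlantRatioError,
    NoPodsError,
)
from .exposure import ExposureAssumptions, ExposureEstimate, daily_exposure
from .hazard_screen import ScreenResult, ScreenVerdict, screen_substance
from .safety_limit import SafetyLimit, derive_safety_limit, select_governing_limit
from .ttc_router import TtcResult, load_ttc_limits, route_ttc
from .units import ug_per_day_to_mg_per_day


class RiskVerdictKind(str, enum.Enum):
    EXCLUDED = "excluded"
    LOW_RISK = "low_risk"
    EXCEEDS_LIMIT = "exceeds_limit"
    INSUFFICIENT_DATA = "insufficient_data"


class LimitSource(str, enum.Enum):
    POD_DERIVED = "pod_derived"
    TTC = "ttc"


EXCEEDANCE_GUIDANCE = (
    "Exposure exceeds the safety limit. Options: (1) remove the additive or reduce "
    "its concentration; (2) have an experienced risk assessor conduct a more refined "
    "risk assessment; (3) generate the data needed for a full toxicological risk "
    "assessment."
)


class RiskVerdict(BaseModel):
    verdict: RiskVerdictKind
    exposure_mg_per_day: float = Field(ge=0)
    governing_limit_mg_per_day: Optional[float] = None
    limit_source: Optional[LimitSource] = None
    margin: Optional[float] = None  # limit / exposure; undefined at zero exposure
    max_allowable_concentration_pct: Optional[float] = None
    screen: ScreenResult
    guidance: Optional[str] = None
    audit: list[dict] = Field(default_factory=list)


def max_allowable_concentration(
    limit_mg_per_day: float, consumption_mg_per_day: float
) -> float:
    """Back-calculate the highest low-risk additive concentration (% w/w)."""
    if consumption_mg_per_day <= 0:
        raise ValueError("consumption must be positive to back-calculate a concentration")
    if limit_mg_per_day < 0:
        raise ValueError("limit must be >= 0")
    pct = limit_mg_per_day / consumption_mg_per_day * 100.0
    if pct > 100.0:
        warnings.warn(
            f"back-calculated concentration {pct:.3g}% w/w exceeds 100%: the safety "
            "limit cannot be reached at any formulation; capped at 100%",
            stacklevel=2,
        )
        return 100.0
    return pct


def characterize_risk(
    exposure: ExposureEstimate,
    limit_mg_per_day: Optional[float],
    screen: ScreenResult,
    limit_source: Optional[LimitSource] = None,
    audit: Optional[AuditLog] = None,
) -> RiskVerdict:
    """Compare exposure with the governing limit (equality counts as low risk)."""
    audit = audit or AuditLog()
    if screen.verdict is ScreenVerdict.EXCLUDE:
        audit.add("characterize", "substance excluded at screening; no limit comparison")
        return RiskVerdict(
            verdict=RiskVerdictKind.EXCLUDED,
            exposure_mg_per_day=exposure.additive_mg_per_day,
            screen=screen,
            audit=audit.to_list(),
        )
    if limit_mg_per_day is None or limit_mg_per_day <= 0:
        raise ValueError("a positive limit is required unless the screen excludes")
    exp = exposure.additive_mg_per_day
    margin = limit_mg_per_day / exp if exp > 0 else None
    if exp == limit_mg_per_day:
        audit.add(
            "boundary_warning",
            "exposure equals the safety limit exactly; treated as low risk by the "
            "documented ≤ convention — verify measurement precision",
        )
    if exp <= limit_mg_per_day:
        verdict, guidance = RiskVerdictKind.LOW_RISK, None
    else:
        verdict, guidance = RiskVerdictKind.EXCEEDS_LIMIT, EXCEEDANCE_GUIDANCE
    audit.add(
        "characterize",
        f"exposure {exp:g} mg/day vs limit {limit_mg_per_day:g} mg/day → {verdict.value}",
    )
    return RiskVerdict(
        verdict=verdict,
        exposure_mg_per_day=exp,
        governing_limit_mg_per_day=limit_mg_per_day,
        limit_source=limit_source,
        margin=margin,
        screen=screen,
        guidance=guidance,
        audit=audit.to_list(),
    )


class AssessmentReport(BaseModel):
    """Self-contained assessment record: inputs echoed, verdict, audit trail."""

    schema_version: str = "1"
    package_version: str = _package_version
    ttc_table_version: str
    dossier: SubstanceDossier
    context: ProductContext
    assumptions: ExposureAssumptions
    concentration_mg_per_g: float
    verdict: RiskVerdict
    ttc: Optional[TtcResult] = None

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    def to_text(self) -> str:
        v = self.verdict
        lines = [
            f"First-tier additive risk assessment — {self.dossier.name}",
            f"  screening verdict: {v.screen.verdict.value}",
        ]
        for reason in v.screen.reasons:
            lines.append(f"    - [{reason.rule}] {reason.text}")
        lines.append(
            f"  additive concentration: {self.concentration_mg_per_g:g} mg/g "
            f"({self.concentration_mg_per_g / 10:g}% w/w)"
        )
        lines.append(f"  daily exposure: {v.exposure_mg_per_day:.3g} mg/day")
        if v.governing_limit_mg_per_day is not None:
            lines.append(
                f"  governing limit: {v.governing_limit_mg_per_day:.3g} mg/day "
                f"({v.limit_source.value if v.limit_source else 'n/a'})"
            )
        if v.margin is not None:
            lines.append(f"  margin (limit/exposure): {v.margin:.3g}")
        if v.max_allowable_concentration_pct is not None:
            lines.append(
                f"  max allowable concentration: "
                f"{v.max_allowable_concentration_pct:.3g}% w/w"
            )
        lines.append(f"  verdict: {v.verdict.value}")
        if v.guidance:
            lines.append(f"  guidance: {v.guidance}")
        return "\n".join(lines)


def run_assessment(
    dossier: SubstanceDossier,
    context: ProductContext,
    assumptions: Optional[ExposureAssumptions] = None,
    concentration_mg_per_g: float = 0.0,
    strict_genotoxicity: bool = False,
    conservative_ttc: bool = False,
) -> AssessmentReport:
    """Run the full first-tier pipeline and assemble the report.

    Pipeline: screen → (POD path if usable PODs exist, else TTC route) →
    daily exposure → risk characterization → maximum-allowable-concentration
    back-calculation. No silent passes: when neither a POD-derived limit nor
    a TTC limit is available the verdict is ``insufficient_data``.
    """
    assumptions = assumptions or ExposureAssumptions()
    audit = AuditLog()
    ttc_table = load_ttc_limits()

    screen = screen_substance(dossier, context, strict_genotoxicity=strict_genotoxicity)
    audit.add(
        "screen",
        f"screening verdict {screen.verdict.value}"
        + (f" (cap {screen.cap_concentration_mg_per_g:g} mg/g)"
           if screen.cap_concentration_mg_per_g is not None else ""),
        rules=[r.rule for r in screen.reasons],
    )
    exposure = daily_exposure(concentration_mg_per_g, assumptions.daily_consumption_mg)
    audit.add(
        "exposure",
        f"daily exposure {exposure.additive_mg_per_day:g} mg/day at "
        f"{concentration_mg_per_g:g} mg/g and "
        f"{assumptions.daily_consumption_mg:g} mg/day consumption",
    )

    def report(verdict: RiskVerdict, ttc: Optional[TtcResult] = None) -> AssessmentReport:
        return AssessmentReport(
            ttc_table_version=ttc_table["version"],
            dossier=dossier,
            context=context,
            assumptions=assumptions,
            concentration_mg_per_g=concentration_mg_per_g,
            verdict=verdict,
            ttc=ttc,
        )

    if screen.verdict is ScreenVerdict.EXCLUDE:
        return report(characterize_risk(exposure, None, screen, audit=audit))

    # dose-response: POD path when PODs exist, else TTC
    limit_mg_day: Optional[float] = None
    limit_source: Optional[LimitSource] = None
    ttc_result: Optional[TtcResult] = None

    if dossier.pods:
        if dossier.genotoxicity_alert:
            audit.add(
                "genotoxicity_note",
                "genotoxicity alert present but PODs are available: POD path taken "
                "per the pipeline order; expert review of the genotoxic TTC tier advised",
            )
        candidates: list[SafetyLimit] = []
        for pod in dossier.pods:
            try:
                candidates.append(
                    derive_safety_limit(pod, dossier, context, assumptions, audit)
                )
            except InsufficientDataError as exc:
                audit.add(
                    "discard_pod",
                    f"{pod.pod_type.value} POD discarded: {exc}",
                )
        if candidates:
            governing = select_governing_limit(candidates, audit)
            limit_mg_day = governing.value_mg_per_day
            limit_source = LimitSource.POD_DERIVED

    if limit_mg_day is None:
        try:
            ttc_result = route_ttc(dossier, context, conservative=conservative_ttc)
        except ClassificationRequiredError as exc:
            audit.add("ttc", f"TTC routing failed: {exc}")
            ttc_result = None
        if ttc_result is not None and ttc_result.applicable:
            limit_mg_day = ug_per_day_to_mg_per_day(ttc_result.limit_ug_per_day)
            limit_source = LimitSource.TTC
            audit.add(
                "ttc",
                f"TTC category {ttc_result.category.value}: "
                f"{ttc_result.limit_ug_per_day:g} µg/day = {limit_mg_day:g} mg/day",
                rationale=ttc_result.rationale,
            )
        elif ttc_result is not None:
            audit.add(
                "ttc",
                "TTC not applicable: " + "; ".join(ttc_result.rationale),
            )

    if limit_mg_day is None:
        audit.add(
            "insufficient_data",
            "no usable POD-derived limit and no applicable TTC limit: a first-tier "
            "numeric assessment is not possible; generate data or consult an expert",
        )
        verdict = RiskVerdict(
            verdict=RiskVerdictKind.INSUFFICIENT_DATA,
            exposure_mg_per_day=exposure.additive_mg_per_day,
            screen=screen,
            guidance=(
                "Insufficient data: no point of departure survived the uncertainty-factor "
                "cap and the TTC approach is not applicable or not classified. This is "
                "never a pass; obtain data or a higher-tier assessment."
            ),
            audit=audit.to_list(),
        )
        return report(verdict, ttc_result)

    verdict = characterize_risk(exposure, limit_mg_day, screen, limit_source, audit)
    mac_pct = max_allowable_concentration(limit_mg_day, assumptions.daily_consumption_mg)
    if screen.cap_concentration_mg_per_g is not None:
        cap_pct = screen.cap_concentration_mg_per_g / 10.0  # mg/g → % w/w
        if cap_pct < mac_pct:
            mac_pct = cap_pct
            audit.add(
                "native_sensitizer_cap",
                f"max allowable concentration tightened to the plant-relative "
                f"sensitizer cap {cap_pct:g}% w/w",
            )
        if concentration_mg_per_g == screen.cap_concentration_mg_per_g:
            audit.add(
                "cap_boundary_warning",
                "formulated concentration sits exactly at the plant-relative cap",
            )
        elif concentration_mg_per_g > screen.cap_concentration_mg_per_g:
            verdict = verdict.model_copy(
                update={
                    "verdict": RiskVerdictKind.EXCEEDS_LIMIT,
                    "guidance": "Concentration exceeds the plant-relative cap for a "
                    "cannabis-native respiratory sensitizer. " + EXCEEDANCE_GUIDANCE,
                }
            )
            audit.add(
                "native_sensitizer_cap",
                f"concentration {concentration_mg_per_g:g} mg/g exceeds the "
                f"plant-relative cap {screen.cap_concentration_mg_per_g:g} mg/g",
            )
    verdict = verdict.model_copy(
        update={"max_allowable_concentration_pct": mac_pct, "audit": audit.to_list()}
    )
    return report(verdict, ttc_result)
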