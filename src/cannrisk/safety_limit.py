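"""Safety-limit derivation from a point of departure.

The first-tier safety limit is

    safety limit = POD_adj / (UF1 × UF2 × UF3 × UF4 × UF5 × UF6)

where POD_adj is the study POD adjusted to continuous exposure (× h/24 for
inhalation, × d/7 for intermittent dosing) and for test-article purity, and
the six uncertainty factors cover interspecies extrapolation, intraspecies
variation, oral→inhalation route extrapolation, LOAEL→NOAEL extrapolation,
study-duration extrapolation, and database completeness (developmental
data). The total uncertainty factor may not exceed 10,000 — beyond that the
data are considered insufficient for a numeric limit and the TTC route is
recommended instead.

Limits are normalized to mg/day for comparison: mg/kg-bw/day limits scale by
the 60 kg body-weight assumption; air concentrations scale by the inhalation
volume matching their averaging window (0.3 m³/15 min, 6.7 m³/workday,
20 m³/24 h). Local-respiratory and systemic endpoints are governed
separately and the lower normalized limit wins; within a track a NOAEL may
only govern if it lies below every LOAEL.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .audit import AuditLog
from .dossier_io import (
    DurationClass,
    EndpointScope,
    PodRecord,
    PodType,
    PodUnits,
    ProductContext,
    RegulatoryWindow,
    Route,
    SensitiveSubpopulation,
    Species,
    SubstanceDossier,
)
from .errors import InsufficientDataError, NoPodsError, UnitError, UnsupportedRouteError
from .exposure import ExposureAssumptions

UF_PRODUCT_CAP = 10_000

ALLOWED_UF_VALUES = {
    "uf1_interspecies": {1, 10},
    "uf2_intraspecies": {1, 3, 10},
    "uf3_route": {1, 2, 3, 6},
    "uf4_loael_to_noael": {1, 10},
    "uf5_duration": {1, 3, 10},
    "uf6_database": {1, 3, 10},
}

_LOAEL_TYPES = {PodType.LOAEL, PodType.LOAEC}


class UncertaintyLedger(BaseModel):
    """The six uncertainty factors with per-factor provenance text."""

    model_config = ConfigDict(extra="forbid")

    uf1_interspecies: int = 1
    uf2_intraspecies: int = 1
    uf3_route: int = 1
    uf4_loael_to_noael: int = 1
    uf5_duration: int = 1
    uf6_database: int = 1
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _values_in_allowed_sets(self) -> "UncertaintyLedger":
        for field, allowed in ALLOWED_UF_VALUES.items():
            value = getattr(self, field)
            if value not in allowed:
                raise ValueError(f"{field} must be one of {sorted(allowed)}, got {value}")
        return self

    def factors(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.uf1_interspecies,
            self.uf2_intraspecies,
            self.uf3_route,
            self.uf4_loael_to_noael,
            self.uf5_duration,
            self.uf6_database,
        )

    @property
    def product(self) -> int:
        p = 1
        for f in self.factors():
            p *= f
        return p


class SafetyLimit(BaseModel):
    """A derived limit in the POD's native units, optionally normalized to mg/day."""

    value_native_units: float = Field(gt=0)
    units: PodUnits
    value_mg_per_day: Optional[float] = Field(default=None, gt=0)
    # adjusted POD normalized to mg/day; used for NOAEL-vs-LOAEL governing
    pod_mg_per_day: Optional[float] = Field(default=None, gt=0)
    governing_pod: PodRecord
    ledger: UncertaintyLedger
    endpoint_scope: EndpointScope


def adjust_pod(pod: PodRecord) -> PodRecord:
    """Adjust a study POD to continuous exposure and test-article purity.

    value × (hours/24 if inhalation) × (days/7) × purity. Regulatory limits
    are window-converted, never schedule-adjusted; they are rejected here.
    """
    if pod.pod_type is PodType.REGULATORY_LIMIT:
        raise ValueError(
            "regulatory limits are converted with normalize_limit_to_mg_per_day, "
            "not schedule-adjusted"
        )
    factor = pod.days_per_week / 7.0 * pod.test_article_purity
    if pod.route is Route.INHALATION:
        factor *= pod.hours_per_day / 24.0
    return pod.model_copy(update={"value": pod.value * factor})


def build_uf_ledger(
    pod: PodRecord, dossier: SubstanceDossier, context: ProductContext
) -> UncertaintyLedger:
    """Assemble the six default uncertainty factors for one POD.

    The ledger is always constructed; the 10,000 cap is enforced when the
    limit is computed. Categories the source limit already addresses are
    forced to 1.
    """
    prov: dict[str, str] = {}

    if pod.species is Species.ANIMAL:
        uf1, prov["uf1_interspecies"] = 10, "animal study: default interspecies factor"
    else:
        uf1, prov["uf1_interspecies"] = 1, "human study: no interspecies extrapolation"

    if pod.tested_sensitive_subpopulation is SensitiveSubpopulation.STRONG:
        uf2 = 1
        prov["uf2_intraspecies"] = "study conducted in a strongly sensitive subpopulation"
    elif pod.tested_sensitive_subpopulation is SensitiveSubpopulation.MODERATE:
        uf2 = 3
        prov["uf2_intraspecies"] = "study conducted in a moderately sensitive subpopulation"
    else:
        uf2, prov["uf2_intraspecies"] = 10, "default intraspecies variation"

    if pod.route is Route.INHALATION:
        uf3, prov["uf3_route"] = 1, "inhalation study: no route extrapolation"
    elif pod.route is Route.ORAL:
        if pod.oral_to_inhalation_absorption_ratio is not None:
            uf3 = 3
            prov["uf3_route"] = (
                "oral to inhalation: measured absorption ratio "
                f"({pod.oral_to_inhalation_absorption_ratio:g}) replaces the toxicokinetic "
                "factor 2; toxicodynamic factor 3 retained"
            )
        else:
            uf3 = 6
            prov["uf3_route"] = (
                "oral to inhalation without absorption data: toxicokinetic 2 × toxicodynamic 3"
            )
    else:
        raise UnsupportedRouteError(
            "no extrapolation factors are defined for dermal PODs; use an oral or "
            "inhalation study"
        )

    if pod.pod_type in _LOAEL_TYPES:
        uf4, prov["uf4_loael_to_noael"] = 10, "adverse effects at lowest tested dose (LOAEL/LOAEC)"
    else:
        uf4, prov["uf4_loael_to_noael"] = 1, "POD is a no-effect level"

    if pod.duration_class is DurationClass.SUBACUTE:
        uf5, prov["uf5_duration"] = 10, "subacute to chronic extrapolation"
    elif pod.duration_class is DurationClass.SUBCHRONIC:
        uf5, prov["uf5_duration"] = 3, "subchronic to chronic extrapolation"
    else:
        uf5, prov["uf5_duration"] = 1, "chronic/lifetime study"

    if dossier.developmental_data_available:
        uf6, prov["uf6_database"] = 1, "developmental/reproductive data available"
    elif context.age_gated:
        uf6, prov["uf6_database"] = 1, "age-gated product: database factor waived"
    elif dossier.developmental_structural_alert is False:
        uf6 = 3
        prov["uf6_database"] = (
            "no developmental data, structure not suggestive of developmental toxicity"
        )
    else:
        uf6 = 10
        prov["uf6_database"] = "no developmental data for a non-age-gated product"

    values = {
        "uf1_interspecies": uf1,
        "uf2_intraspecies": uf2,
        "uf3_route": uf3,
        "uf4_loael_to_noael": uf4,
        "uf5_duration": uf5,
        "uf6_database": uf6,
    }
    for category in sorted(pod.uf_categories_already_addressed):
        field = list(values)[category - 1]
        values[field] = 1
        prov[field] = "addressed by source limit"

    return UncertaintyLedger(**values, provenance=prov)


def compute_safety_limit(adjusted_pod: PodRecord, ledger: UncertaintyLedger) -> SafetyLimit:
    """Divide the adjusted POD by the total uncertainty factor (native units)."""
    if ledger.product > UF_PRODUCT_CAP:
        raise InsufficientDataError(
            f"total uncertainty factor {ledger.product} exceeds the {UF_PRODUCT_CAP} cap: "
            "there is likely insufficient information for a numeric safety limit; "
            "consider the TTC approach or a higher-tier assessment"
        )
    return SafetyLimit(
        value_native_units=adjusted_pod.value / ledger.product,
        units=adjusted_pod.units,
        governing_pod=adjusted_pod,
        ledger=ledger,
        endpoint_scope=adjusted_pod.endpoint_scope,
    )


def normalize_limit_to_mg_per_day(
    value: float,
    units: PodUnits,
    window: RegulatoryWindow = RegulatoryWindow.NOT_APPLICABLE,
    assumptions: Optional[ExposureAssumptions] = None,
) -> float:
    """Convert a limit (or regulatory POD) to mg/day under the assumption set.

    mg/kg-bw/day scales by body weight; mg/m³ scales by the inhalation volume
    for its averaging window; mg/day is the identity.
    """
    assumptions = assumptions or ExposureAssumptions()
    if units is PodUnits.MG_PER_DAY:
        return value
    if units is PodUnits.MG_PER_KG_BW_PER_DAY:
        return value * assumptions.body_weight_kg
    if units is PodUnits.MG_PER_M3:
        volumes = {
            RegulatoryWindow.STEL_15MIN: assumptions.inhalation_volume_15min_m3,
            RegulatoryWindow.TWA_8H: assumptions.inhalation_volume_8h_m3,
            RegulatoryWindow.CONTINUOUS_24H: assumptions.inhalation_volume_24h_m3,
        }
        if window not in volumes:
            raise UnitError(
                "an mg/m³ limit needs an averaging window (stel_15min, twa_8h or "
                "continuous_24h) to pick the inhaled volume"
            )
        return value * volumes[window]
    raise UnitError(f"cannot normalize units {units}")  # pragma: no cover


def derive_safety_limit(
    pod: PodRecord,
    dossier: SubstanceDossier,
    context: ProductContext,
    assumptions: Optional[ExposureAssumptions] = None,
    audit: Optional[AuditLog] = None,
) -> SafetyLimit:
    """Full per-POD derivation: adjust → ledger → limit → normalize to mg/day.

    Regulatory limits skip schedule adjustment: they are window-converted to
    mg/day first and UF categories they already address are forced to 1.
    """
    assumptions = assumptions or ExposureAssumptions()
    audit = audit or AuditLog()
    ledger = build_uf_ledger(pod, dossier, context)

    if pod.pod_type is PodType.REGULATORY_LIMIT:
        pod_mg_day = normalize_limit_to_mg_per_day(
            pod.value, pod.units, pod.regulatory_window, assumptions
        )
        audit.add(
            "normalize_regulatory_limit",
            f"regulatory limit {pod.value:g} {pod.units.value} "
            f"({pod.regulatory_window.value}) → {pod_mg_day:g} mg/day",
        )
        if ledger.product > UF_PRODUCT_CAP:
            raise InsufficientDataError(
                f"total uncertainty factor {ledger.product} exceeds the {UF_PRODUCT_CAP} cap"
            )
        value = pod_mg_day / ledger.product
        limit = SafetyLimit(
            value_native_units=value,
            units=PodUnits.MG_PER_DAY,
            value_mg_per_day=value,
            pod_mg_per_day=pod_mg_day,
            governing_pod=pod,
            ledger=ledger,
            endpoint_scope=pod.endpoint_scope,
        )
    else:
        adjusted = adjust_pod(pod)
        audit.add(
            "adjust_pod",
            f"{pod.pod_type.value} {pod.value:g} {pod.units.value} adjusted to "
            f"{adjusted.value:g} (schedule {pod.hours_per_day:g} h/day, "
            f"{pod.days_per_week:g} d/week; purity {pod.test_article_purity:g})",
        )
        if (
            pod.route is Route.ORAL
            and pod.oral_to_inhalation_absorption_ratio is not None
        ):
            adjusted = adjusted.model_copy(
                update={"value": adjusted.value * pod.oral_to_inhalation_absorption_ratio}
            )
            audit.add(
                "absorption_adjustment",
                "adjusted POD scaled by measured oral:inhalation absorption ratio "
                f"{pod.oral_to_inhalation_absorption_ratio:g}",
            )
        limit = compute_safety_limit(adjusted, ledger)
        # after the h/24 adjustment an air concentration is continuous-equivalent
        window = (
            RegulatoryWindow.CONTINUOUS_24H
            if limit.units is PodUnits.MG_PER_M3
            else RegulatoryWindow.NOT_APPLICABLE
        )
        limit = limit.model_copy(
            update={
                "value_mg_per_day": normalize_limit_to_mg_per_day(
                    limit.value_native_units, limit.units, window, assumptions
                ),
                "pod_mg_per_day": normalize_limit_to_mg_per_day(
                    adjusted.value, adjusted.units, window, assumptions
                ),
            }
        )
    audit.add(
        "uncertainty_ledger",
        f"UFs {ledger.factors()} (product {ledger.product}); "
        f"limit {limit.value_mg_per_day:g} mg/day",
        provenance=ledger.provenance,
    )
    return limit


def select_governing_limit(
    candidates: list[SafetyLimit], audit: Optional[AuditLog] = None
) -> SafetyLimit:
    """Pick the governing limit across candidates, all normalized to mg/day.

    Systemic and local-respiratory tracks are evaluated separately; within a
    track any NOAEL/NOAEC candidate whose adjusted POD exceeds some LOAEL's
    adjusted POD is discarded. The minimum normalized limit across the
    survivors of both tracks governs.
    """
    audit = audit or AuditLog()
    if not candidates:
        raise NoPodsError("no safety-limit candidates: use the TTC route instead")
    for c in candidates:
        if c.value_mg_per_day is None or c.pod_mg_per_day is None:
            raise ValueError("candidates must be normalized to mg/day before governing")

    survivors: list[SafetyLimit] = []
    for scope in EndpointScope:
        track = [c for c in candidates if c.endpoint_scope is scope]
        if not track:
            continue
        loael_pods = [c.pod_mg_per_day for c in track if c.governing_pod.pod_type in _LOAEL_TYPES]
        for c in track:
            if (
                c.governing_pod.pod_type in {PodType.NOAEL, PodType.NOAEC}
                and loael_pods
                and c.pod_mg_per_day > min(loael_pods)
            ):
                audit.add(
                    "discard_candidate",
                    f"{scope.value}: {c.governing_pod.pod_type.value} POD "
                    f"{c.pod_mg_per_day:g} mg/day exceeds a LOAEL at "
                    f"{min(loael_pods):g} mg/day; LOAEL-based candidate governs",
                )
            else:
                survivors.append(c)
    if not survivors:  # pragma: no cover - defensive; a LOAEL always survives
        raise NoPodsError("all candidates were discarded")
    governing = min(survivors, key=lambda c: c.value_mg_per_day)
    audit.add(
        "governing_limit",
        f"governing limit {governing.value_mg_per_day:g} mg/day "
        f"({governing.endpoint_scope.value} track, "
        f"{governing.governing_pod.pod_type.value} POD)",
    )
    return governing
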