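"""POD adjustment, uncertainty-factor ledger, limit computation and governing."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cannrisk.dossier_io import (
    DurationClass,
    EndpointScope,
    PodType,
    PodUnits,
    ProductContext,
    RegulatoryWindow,
    Route,
    SensitiveSubpopulation,
    Species,
)
from cannrisk.errors import InsufficientDataError, NoPodsError, UnitError, UnsupportedRouteError
from cannrisk.exposure import ExposureAssumptions
from cannrisk.safety_limit import (
    ALLOWED_UF_VALUES,
    UncertaintyLedger,
    adjust_pod,
    build_uf_ledger,
    compute_safety_limit,
    derive_safety_limit,
    normalize_limit_to_mg_per_day,
    select_governing_limit,
)


class TestAdjustPod:
    def test_intermittent_inhalation_schedule(self, make_pod):
        pod = make_pod(
            value=100.0,
            units=PodUnits.MG_PER_M3,
            pod_type=PodType.NOAEC,
            route=Route.INHALATION,
            hours_per_day=6,
            days_per_week=5,
        )
        assert adjust_pod(pod).value == pytest.approx(100 * 6 / 24 * 5 / 7)

    def test_continuous_oral_dosing_unchanged(self, make_pod):
        assert adjust_pod(make_pod(value=50.0)).value == 50.0

    def test_purity_scales_the_pod(self, make_pod):
        assert adjust_pod(make_pod(value=100.0, test_article_purity=0.9)).value == pytest.approx(90.0)

    def test_hours_ignored_for_oral_route(self, make_pod):
        # gavage 1 h/day is still a full daily dose; only days/week matter
        assert adjust_pod(make_pod(value=70.0, hours_per_day=1, days_per_week=7)).value == 70.0

    def test_regulatory_limits_are_not_schedule_adjusted(self, make_pod):
        pod = make_pod(
            pod_type=PodType.REGULATORY_LIMIT,
            units=PodUnits.MG_PER_M3,
            regulatory_window=RegulatoryWindow.TWA_8H,
            route=Route.INHALATION,
        )
        with pytest.raises(ValueError, match="normalize_limit_to_mg_per_day"):
            adjust_pod(pod)


class TestUfLedger:
    def test_rat_subchronic_oral_noael_defaults(self, make_pod, make_dossier):
        ledger = build_uf_ledger(
            make_pod(),
            make_dossier(developmental_data_available=True),
            ProductContext(age_gated=True),
        )
        assert ledger.factors() == (10, 10, 6, 1, 3, 1)
        assert ledger.product == 1800

    def test_human_chronic_inhalation_noaec(self, make_pod, make_dossier):
        pod = make_pod(
            units=PodUnits.MG_PER_M3,
            pod_type=PodType.NOAEC,
            route=Route.INHALATION,
            species=Species.HUMAN,
            duration_class=DurationClass.CHRONIC,
        )
        ledger = build_uf_ledger(pod, make_dossier(), ProductContext(age_gated=True))
        assert ledger.factors() == (1, 10, 1, 1, 1, 1)
        assert ledger.product == 10

    def test_worst_case_subacute_oral_loael(self, make_pod, make_dossier):
        pod = make_pod(pod_type=PodType.LOAEL, duration_class=DurationClass.SUBACUTE)
        ledger = build_uf_ledger(pod, make_dossier(), ProductContext(age_gated=False))
        assert ledger.product == 10 * 10 * 6 * 10 * 10 * 10  # 600,000: cap fires downstream

    @pytest.mark.parametrize(
        "subpop, expected",
        [
            (SensitiveSubpopulation.NONE, 10),
            (SensitiveSubpopulation.MODERATE, 3),
            (SensitiveSubpopulation.STRONG, 1),
        ],
    )
    def test_intraspecies_relief_requires_sensitive_subpopulation(
        self, make_pod, make_dossier, context, subpop, expected
    ):
        pod = make_pod(tested_sensitive_subpopulation=subpop)
        assert build_uf_ledger(pod, make_dossier(), context).uf2_intraspecies == expected

    def test_absorption_data_replace_toxicokinetic_route_factor(
        self, make_pod, make_dossier, context
    ):
        pod = make_pod(oral_to_inhalation_absorption_ratio=0.5)
        assert build_uf_ledger(pod, make_dossier(), context).uf3_route == 3

    def test_structural_alert_tristate_drives_database_factor(
        self, make_pod, make_dossier
    ):
        ctx = ProductContext(age_gated=False)
        assert build_uf_ledger(make_pod(), make_dossier(), ctx).uf6_database == 10
        relieved = make_dossier(developmental_structural_alert=False)
        assert build_uf_ledger(make_pod(), relieved, ctx).uf6_database == 3

    def test_source_limit_categories_forced_to_one(self, make_pod, make_dossier, context):
        pod = make_pod(uf_categories_already_addressed={1, 2, 3})
        ledger = build_uf_ledger(pod, make_dossier(), context)
        assert ledger.factors()[:3] == (1, 1, 1)
        assert ledger.provenance["uf1_interspecies"] == "addressed by source limit"

    def test_dermal_route_is_rejected(self, make_pod, make_dossier, context):
        with pytest.raises(UnsupportedRouteError):
            build_uf_ledger(make_pod(route=Route.DERMAL), make_dossier(), context)

    def test_ledger_rejects_values_outside_enumerated_sets(self):
        with pytest.raises(ValueError):
            UncertaintyLedger(uf1_interspecies=5)


class TestComputeLimit:
    def test_division_by_ledger_product(self, make_pod):
        ledger = UncertaintyLedger(
            uf1_interspecies=10, uf2_intraspecies=10, uf3_route=6, uf5_duration=3
        )
        limit = compute_safety_limit(make_pod(value=18.0), ledger)
        assert limit.value_native_units == pytest.approx(0.01)

    def test_all_ones_ledger_is_identity(self, make_pod):
        pod = make_pod(value=7.0)
        assert compute_safety_limit(pod, UncertaintyLedger()).value_native_units == 7.0

    def test_cap_refuses_numeric_limit(self, make_pod):
        ledger = UncertaintyLedger(
            uf1_interspecies=10,
            uf2_intraspecies=10,
            uf3_route=6,
            uf4_loael_to_noael=10,
            uf5_duration=10,
            uf6_database=10,
        )
        with pytest.raises(InsufficientDataError, match="TTC"):
            compute_safety_limit(make_pod(), ledger)


class TestNormalize:
    def test_occupational_twa_conversion(self):
        # 8-h TWA of 135 mg/m³ at 6.7 m³ workday inhalation volume
        assert normalize_limit_to_mg_per_day(
            135, PodUnits.MG_PER_M3, RegulatoryWindow.TWA_8H
        ) == pytest.approx(904.5)

    def test_sensitizer_stel_conversion(self):
        # 15-min STEL of 0.002 mg/m³ at 0.3 m³ → 0.6 µg/day
        value = normalize_limit_to_mg_per_day(
            0.002, PodUnits.MG_PER_M3, RegulatoryWindow.STEL_15MIN
        )
        assert value == pytest.approx(0.0006)

    def test_body_weight_conversion(self):
        assert normalize_limit_to_mg_per_day(
            0.01, PodUnits.MG_PER_KG_BW_PER_DAY
        ) == pytest.approx(0.6)

    def test_mg_per_day_is_identity(self):
        assert normalize_limit_to_mg_per_day(3.2, PodUnits.MG_PER_DAY) == 3.2

    def test_air_concentration_without_window_is_an_error(self):
        with pytest.raises(UnitError):
            normalize_limit_to_mg_per_day(1.0, PodUnits.MG_PER_M3)


class TestGoverning:
    def _candidate(self, make_pod, make_dossier, **pod_kw):
        dossier = make_dossier(developmental_data_available=True)
        return derive_safety_limit(
            make_pod(**pod_kw), dossier, ProductContext(age_gated=True)
        )

    def test_local_respiratory_track_governs_when_lower(self, make_pod, make_dossier):
        systemic = self._candidate(make_pod, make_dossier, value=9000.0)
        local = self._candidate(
            make_pod,
            make_dossier,
            value=100.0,
            units=PodUnits.MG_PER_M3,
            pod_type=PodType.NOAEC,
            route=Route.INHALATION,
            endpoint_scope=EndpointScope.LOCAL_RESPIRATORY,
        )
        governing = select_governing_limit([systemic, local])
        assert governing.endpoint_scope is EndpointScope.LOCAL_RESPIRATORY
        assert governing.value_mg_per_day == min(
            systemic.value_mg_per_day, local.value_mg_per_day
        )

    def test_single_candidate_governs_itself(self, make_pod, make_dossier):
        c = self._candidate(make_pod, make_dossier)
        assert select_governing_limit([c]) is c

    def test_noael_above_loael_is_discarded(self, make_pod, make_dossier):
        """A NOAEL may govern only if below every LOAEL in its track.

        Built so the NOAEL-derived limit is the lower number (heavier UFs):
        a plain minimum would pick it, but its POD (50) sits above the LOAEL
        POD (30), so the discard rule must hand governance to the LOAEL.
        """
        noael = self._candidate(
            make_pod, make_dossier, value=50.0, duration_class=DurationClass.SUBACUTE
        )
        loael = self._candidate(
            make_pod,
            make_dossier,
            value=30.0,
            pod_type=PodType.LOAEL,
            species=Species.HUMAN,
            duration_class=DurationClass.CHRONIC,
        )
        assert noael.value_mg_per_day < loael.value_mg_per_day  # min() alone would err
        governing = select_governing_limit([noael, loael])
        assert governing.governing_pod.pod_type is PodType.LOAEL

    def test_noael_below_all_loaels_is_not_discarded(self, make_pod, make_dossier):
        from cannrisk.audit import AuditLog

        noael = self._candidate(
            make_pod, make_dossier, value=10.0, duration_class=DurationClass.CHRONIC
        )
        loael = self._candidate(
            make_pod,
            make_dossier,
            value=30.0,
            pod_type=PodType.LOAEL,
            duration_class=DurationClass.CHRONIC,
        )
        audit = AuditLog()
        governing = select_governing_limit([noael, loael], audit)
        assert not any(e["step"] == "discard_candidate" for e in audit)
        assert governing.value_mg_per_day == min(
            noael.value_mg_per_day, loael.value_mg_per_day
        )

    def test_empty_candidates_direct_to_ttc(self):
        with pytest.raises(NoPodsError, match="TTC"):
            select_governing_limit([])


class TestDerive:
    def test_regulatory_limit_window_converted_and_uf_divided(self, make_pod, make_dossier):
        pod = make_pod(
            value=135.0,
            pod_type=PodType.REGULATORY_LIMIT,
            units=PodUnits.MG_PER_M3,
            regulatory_window=RegulatoryWindow.TWA_8H,
            route=Route.INHALATION,
            species=Species.HUMAN,
            duration_class=DurationClass.CHRONIC,
            uf_categories_already_addressed={2},
        )
        limit = derive_safety_limit(pod, make_dossier(), ProductContext(age_gated=True))
        # 904.5 mg/day with every UF addressed or inapplicable → 904.5
        assert limit.value_mg_per_day == pytest.approx(904.5)

    def test_insufficient_data_propagates_from_cap(self, make_pod, make_dossier):
        pod = make_pod(pod_type=PodType.LOAEL, duration_class=DurationClass.SUBACUTE)
        with pytest.raises(InsufficientDataError):
            derive_safety_limit(pod, make_dossier(), ProductContext(age_gated=False))


# ---------------------------------------------------------------------------
# properties

_uf_fields = list(ALLOWED_UF_VALUES)


@st.composite
def ledgers(draw):
    return UncertaintyLedger(
        **{f: draw(st.sampled_from(sorted(ALLOWED_UF_VALUES[f]))) for f in _uf_fields}
    )


@given(ledgers(), st.sampled_from(_uf_fields))
def test_limit_strictly_decreasing_in_each_uf(ledger, field):
    """Raising any single UF strictly lowers the limit (or trips the cap)."""
    from cannrisk.dossier_io import PodRecord

    pod = PodRecord(
        value=100.0,
        units=PodUnits.MG_PER_KG_BW_PER_DAY,
        pod_type=PodType.NOAEL,
        route=Route.ORAL,
        species=Species.ANIMAL,
        duration_class=DurationClass.SUBCHRONIC,
    )
    allowed = sorted(ALLOWED_UF_VALUES[field])
    current = getattr(ledger, field)
    higher = [v for v in allowed if v > current]
    if not higher:
        return
    bumped = ledger.model_copy(update={field: higher[0]})

    def limit_of(lg):
        try:
            return compute_safety_limit(pod, lg).value_native_units
        except InsufficientDataError:
            return None

    a, b = limit_of(ledger), limit_of(bumped)
    if a is not None and b is not None:
        assert b < a


@given(st.floats(min_value=1e-3, max_value=1e6, allow_nan=False), st.floats(min_value=0.1, max_value=10))
def test_limit_homogeneous_of_degree_one_in_pod(value, scale):
    """Scaling the POD value scales the derived limit by the same factor."""
    from cannrisk.dossier_io import PodRecord

    def pipeline(v):
        pod = PodRecord(
            value=v,
            units=PodUnits.MG_PER_KG_BW_PER_DAY,
            pod_type=PodType.NOAEL,
            route=Route.ORAL,
            species=Species.ANIMAL,
            duration_class=DurationClass.SUBCHRONIC,
            hours_per_day=6,
            days_per_week=5,
            test_article_purity=0.9,
        )
        ledger = UncertaintyLedger(uf1_interspecies=10, uf5_duration=3)
        return compute_safety_limit(adjust_pod(pod), ledger).value_native_units

    assert pipeline(value * scale) == pytest.approx(pipeline(value) * scale, rel=1e-9)


@given(ledgers())
def test_cap_enforced_for_every_overlarge_ledger(ledger):
    """Every ledger with product > 10,000 refuses a numeric limit; others succeed."""
    from cannrisk.dossier_io import PodRecord

    pod = PodRecord(
        value=1.0,
        units=PodUnits.MG_PER_DAY,
        pod_type=PodType.NOAEL,
        route=Route.INHALATION,
        species=Species.ANIMAL,
        duration_class=DurationClass.CHRONIC,
    )
    if ledger.product > 10_000:
        with pytest.raises(InsufficientDataError):
            compute_safety_limit(pod, ledger)
    else:
        assert compute_safety_limit(pod, ledger).value_native_units > 0


def test_renormalizing_mg_per_day_is_identity():
    assumptions = ExposureAssumptions()
    value = normalize_limit_to_mg_per_day(2.5, PodUnits.MG_PER_DAY, assumptions=assumptions)
    assert normalize_limit_to_mg_per_day(
        value, PodUnits.MG_PER_DAY, assumptions=assumptions
    ) == value
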