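from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from cannrisk.dossier_io import (
    DurationClass,
    PodRecord,
    PodType,
    PodUnits,
    ProductContext,
    Route,
    Species,
    SubstanceDossier,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def make_pod():
    """Factory for a valid POD with overridable fields."""

    def _make(**overrides) -> PodRecord:
        base = dict(
            value=50.0,
            units=PodUnits.MG_PER_KG_BW_PER_DAY,
            pod_type=PodType.NOAEL,
            route=Route.ORAL,
            species=Species.ANIMAL,
            duration_class=DurationClass.SUBCHRONIC,
        )
        base.update(overrides)
        return PodRecord(**base)

    return _make


@pytest.fixture
def make_dossier():
    """Factory for a minimal valid dossier with overridable fields."""

    def _make(**overrides) -> SubstanceDossier:
        base = dict(name="test-substance")
        base.update(overrides)
        return SubstanceDossier(**base)

    return _make


@pytest.fixture
def context():
    return ProductContext()
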