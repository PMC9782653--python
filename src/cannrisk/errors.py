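"""Exception hierarchy for the risk-assessment pipeline."""


class CannriskError(Exception):
    """Base class for all package-specific errors."""


class DossierFormatError(CannriskError):
    """A dossier file could not be parsed (malformed JSON/CSV, bad literal)."""


class DossierValidationError(CannriskError):
    """A dossier parsed but violated one or more model invariants.

    ``violations`` lists every violated invariant, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class MissingPlantRatioError(CannriskError):
    """A cannabis-native sensitizer cap was requested without plant-concentration data."""


class UnsupportedRouteError(CannriskError):
    """No extrapolation factors exist for this exposure route (e.g. dermal)."""


class InsufficientDataError(CannriskError):
    """The total uncertainty factor exceeds the 10,000 cap; a numeric limit is refused."""


class NoPodsError(CannriskError):
    """No point-of-departure candidates were available; caller should try TTC."""


class ClassificationRequiredError(CannriskError):
    """TTC routing reached a question whose answer (Cramer class / OASIS MOA) is unclassified."""


class UnitError(CannriskError):
    """A unit conversion was requested without the information needed to perform it."""
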