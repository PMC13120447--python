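"""Exception hierarchy for assay-data validation and analysis."""


class Epi2SensAError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(Epi2SensAError):
    """An input table is missing mandatory columns or has an unusable layout."""


class RecordValueError(Epi2SensAError):
    """A row holds an unparseable or out-of-range value (row-numbered)."""


class IntegrityError(Epi2SensAError):
    """Duplicate keys or cross-file inconsistencies in the input tables."""


class FixtureError(Epi2SensAError):
    """A packaged data fixture failed its shape/content check."""


class InsolubilityError(Epi2SensAError):
    """No vehicle dissolves the chemical at any tested concentration."""


class DegenerateKilledControlError(Epi2SensAError):
    """Killed-control LDH signal does not exceed the vehicle control.

    The killed control defines 100% LDH release; if its mean delta-absorbance
    is not strictly above the vehicle control's, lysis failed and the
    viability denominator is non-positive.
    """


class MissingReferenceError(Epi2SensAError):
    """A run lacks the control tissues needed as a reference (killed/vehicle)."""


class NormalizationError(Epi2SensAError):
    """A tissue lacks the GAPDH Ct needed for ddCt normalization."""


class StructuralRunError(Epi2SensAError):
    """A run is missing a required role (e.g. a positive control) entirely.

    Distinct from a run-acceptance *failure*: the check could not even be
    evaluated.
    """


class NoDataError(Epi2SensAError):
    """No valid run calls remain after exclusions."""


class UnresolvedModeError(Epi2SensAError):
    """Run calls are tied three ways; no mode exists."""


class ConfigError(Epi2SensAError):
    """Invalid simulation or criteria configuration."""
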