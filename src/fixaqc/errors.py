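"""Exception hierarchy for the fixaqc pipeline."""


class FixaqcError(Exception):
    """Base class for all fixaqc errors."""


class SchemaError(FixaqcError):
    """A gaze-file schema is missing a mandatory column or role."""


class FormatError(FixaqcError):
    """A gaze file violates a structural requirement (e.g. non-monotone time)."""


class IntegrityError(FixaqcError):
    """An event list violates its ordering/overlap contract."""


class UndefinedMetricError(FixaqcError):
    """Too few valid samples to define a quality metric."""


class InsufficientDataError(FixaqcError):
    """Not enough contiguous valid data for the requested computation."""


class DegenerateThresholdError(FixaqcError):
    """The median-based velocity noise scale is zero or non-finite."""


class ConfigError(FixaqcError):
    """An invalid or infeasible configuration value."""
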