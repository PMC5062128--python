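"""Exception hierarchy for the tcrfootprint pipeline.

Every stage raises a subclass of :class:`TcrFootprintError` so the CLI can
report a categorized, stage-attributed failure and exit nonzero.
"""


class TcrFootprintError(Exception):
    """Base class for all package errors."""


class ConfigError(TcrFootprintError):
    """Invalid or inconsistent analysis configuration."""


class SchemaError(TcrFootprintError):
    """An input table is missing a required column or has a bad header."""


class ParseError(TcrFootprintError):
    """A cell in an input table could not be parsed; carries its location."""


class DataValidationError(TcrFootprintError):
    """Parsed data violates an invariant (duplicates, non-positive values...)."""


class FitError(TcrFootprintError):
    """Base class for curve-fitting failures."""


class InsufficientDataError(FitError):
    """Too few points to fit the model."""


class DegenerateDataError(FitError):
    """Data carries no usable signal (flat series, non-decaying trace)."""


class FitConvergenceError(FitError):
    """The optimizer failed to converge after retries."""


class StructureError(TcrFootprintError):
    """A structure file is malformed or inconsistent with the role map."""


class GenerationError(TcrFootprintError):
    """A synthetic scenario requests infeasible geometry or parameters."""
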