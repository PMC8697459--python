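"""Exception hierarchy for the growth-reference pipeline."""


class GrowthRefError(Exception):
    """Base class for all package errors."""


class SchemaError(GrowthRefError):
    """A CSV file is missing required columns or contains unparseable rows."""


class LinkageError(GrowthRefError):
    """A measurement or event references a subject that does not exist."""


class InvariantError(GrowthRefError):
    """A domain object violates one of its structural invariants."""


class ConfigurationError(GrowthRefError):
    """A requested option combination is inconsistent or incomplete."""


class FitError(GrowthRefError):
    """A smoothing fit could not be performed (too few points, etc.)."""


class InsufficientDataError(GrowthRefError):
    """A summary statistic was requested on too few observations."""


class RangeError(GrowthRefError):
    """An index value falls outside a reference table's grid (no extrapolation)."""
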