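"""Exception hierarchy shared across the package."""


class IsofluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidFormulaError(IsofluxError):
    """Elemental formula is inconsistent (e.g. more tracer positions than atoms)."""


class InsufficientRangeError(IsofluxError):
    """Observed mass-shift range K is smaller than the number of tracer positions."""


class EmptyMeasurementError(IsofluxError):
    """A raw isotopologue measurement carries no signal."""


class PhaseError(IsofluxError):
    """A plate assay is missing a required injection phase or has phases out of order."""


class SchemaError(IsofluxError):
    """An input table is missing required columns or violates the documented schema."""


class UniverseError(IsofluxError):
    """Two ranked lists share no identifiers."""


class ParameterError(IsofluxError):
    """An operation was called with an out-of-range parameter."""
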