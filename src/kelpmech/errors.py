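"""Exception hierarchy for the kelpmech pipeline.

Every anticipated failure mode raises a subclass of :class:`KelpmechError`
so callers can distinguish pipeline problems from programming errors.
"""


class KelpmechError(Exception):
    """Base class for all kelpmech errors."""


class DegenerateRecord(KelpmechError):
    """A tensile record is too short or otherwise unusable for an operation."""


class NoFailureDetected(KelpmechError):
    """No sample satisfies the force-drop failure criterion."""


class ExcludedSpecimen(KelpmechError):
    """The specimen was flagged excluded (clamp/cradle failure) upstream."""


class ZeroStrainRange(KelpmechError):
    """Strain is constant within every candidate modulus window."""


class DegenerateInput(KelpmechError):
    """A regression variable is constant (zero variance)."""


class AmbiguousSign(KelpmechError):
    """SMA slope sign is undefined because the correlation is numerically zero."""


class TooFewPoints(KelpmechError):
    """Fewer observations than the regression requires."""


class MissingVariable(KelpmechError):
    """A regression spec names a column absent from the data."""


class NonConvergence(KelpmechError):
    """Iterative breakpoint estimation exceeded the iteration budget."""


class InvalidSpec(KelpmechError):
    """A simulation spec violates its invariants."""


class InconsistentSpec(InvalidSpec):
    """Redundant tensile-curve parameters that contradict each other."""


class ParseError(KelpmechError):
    """An input file could not be parsed; carries file/row context."""


class SchemaError(KelpmechError):
    """An input file is missing mandatory columns."""
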