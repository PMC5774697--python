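"""Exception and warning hierarchy.

Errors are grouped so the CLI can map them onto distinct exit codes:
usage problems, schema problems, and data/measurement problems.
"""


class RenalMorphError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(RenalMorphError, ValueError):
    """An axial measurement or area violates its invariants (e.g. a <= 0)."""


class EmptySectionError(RenalMorphError, ValueError):
    """A mask contains no foreground after preprocessing."""


class DegenerateShapeError(RenalMorphError, ValueError):
    """Foreground is a point or a line; axes are undefined."""


class GenerationError(RenalMorphError, ValueError):
    """Synthetic-shape parameters produced an empty or disconnected mask."""


class ConfigurationError(RenalMorphError, ValueError):
    """A simulation or CLI configuration violates its invariants."""


class SchemaError(RenalMorphError, ValueError):
    """A measurement table is missing required columns or is malformed."""


class UndefinedCorrelationError(RenalMorphError, ValueError):
    """Correlation requested on a constant vector or mismatched lengths."""


class SingularFitError(RenalMorphError, ValueError):
    """Least-squares calibration requested on a constant predictor."""


class RenalMorphWarning(UserWarning):
    """Base class for package warnings."""


class MeasurementWarning(RenalMorphWarning):
    """A measurement is unusual but not invalid (e.g. b_e exceeds a)."""


class CalibrationWarning(RenalMorphWarning):
    """A collagen estimate fell outside the calibration range (negative)."""
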