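"""Exception hierarchy for pulseqc.

Validation-type errors (bad parameters, degenerate inputs) map to CLI exit
code 2; parse/format/IO errors map to exit code 3.
"""


class PulseQCError(Exception):
    """Base class for all pulseqc errors."""


class ValidationError(PulseQCError):
    """Invalid parameter, index, or input that violates a precondition."""


class SchemaError(ValidationError):
    """A structured file is missing required fields."""


class DegenerateInputError(ValidationError):
    """Input too short or otherwise degenerate to process."""


class DegenerateSegmentError(ValidationError):
    """Constant (flatline) segment: amplitude is zero."""


class NoPulseError(ValidationError):
    """Derivative maximum is non-positive: no systolic upstroke present."""


class TooShortSegmentError(ValidationError):
    """Segment has fewer samples than cubic-spline resampling requires."""


class UndefinedMetricError(ValidationError):
    """Sensitivity/specificity undefined because a class is absent."""


class TrainingError(ValidationError):
    """Classifier training impossible (e.g. single-class corpus)."""


class ParseError(PulseQCError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class FormatError(ParseError):
    """File parsed but violates the expected structure (e.g. non-monotone time)."""
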