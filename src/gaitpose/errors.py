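"""Exception hierarchy for the gait-analysis pipeline.

Each stage raises a distinct subclass so callers (and the CLI) can map
failures to actionable diagnostics and exit codes.
"""


class GaitposeError(Exception):
    """Base class for all package errors."""


class SchemaError(GaitposeError):
    """A required landmark column is missing or malformed."""


class FormatError(GaitposeError):
    """The input file violates the keypoint CSV contract (e.g. frame gaps)."""


class ConfigurationError(GaitposeError):
    """An invalid or unresolvable configuration value."""


class DegenerateGeometryError(GaitposeError):
    """Coincident keypoints make an angle undefined."""


class DegenerateSignalError(GaitposeError):
    """The angle signal carries no gait dynamics (e.g. constant)."""


class InsufficientEventsError(GaitposeError):
    """Too few gait events were detected to compute outcomes."""


class CalibrationError(GaitposeError):
    """The static calibration segment is unusable (too short or unstable)."""


class ContractError(GaitposeError):
    """An operation was called with inputs violating its precondition."""


class AlignmentError(GaitposeError):
    """Predicted and reference outcome streams could not be matched."""


class SessionError(GaitposeError):
    """Both body sides failed; aggregates per-side reasons."""

    def __init__(self, reasons: dict):
        self.reasons = dict(reasons)
        super().__init__(
            "analysis failed on all sides: "
            + "; ".join(f"{s}: {r}" for s, r in self.reasons.items())
        )
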