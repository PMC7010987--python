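"""Exception hierarchy for pvohscan.

All errors derive from :class:`PvohError` so callers can catch the package's
failures with a single except clause; the subclasses mirror the distinct
failure modes of the pipeline (bad inputs, degenerate calibrations,
misaligned streams, fit failures).
"""


class PvohError(Exception):
    """Base class for all pvohscan errors."""


class InvalidInputError(PvohError, ValueError):
    """An argument violates a documented precondition."""


class EmptyBandError(InvalidInputError):
    """A spectral integration window lies entirely outside the shift axis."""


class DegenerateCalibrationError(PvohError):
    """The forward model or reference series cannot be inverted (singular /
    rank-deficient)."""


class UndefinedHematocritError(PvohError):
    """Hematocrit requested where phi_r + phi_p <= 0."""


class StreamAlignmentError(PvohError):
    """An emission stream does not match the schedule's frame/block count."""

    def __init__(self, expected: int, received: int, unit: str = "frames"):
        self.expected = expected
        self.received = received
        super().__init__(
            f"stream/schedule mismatch: expected {expected} {unit}, received {received}"
        )


class InvalidProtocolError(PvohError):
    """A scan protocol or schedule is internally inconsistent."""


class InvalidCoordinateError(PvohError):
    """A probed coordinate lies outside the phantom field."""


class FitFailureError(PvohError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
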