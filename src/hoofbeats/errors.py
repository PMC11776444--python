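"""Exception hierarchy shared across the package."""


class HoofbeatsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HoofbeatsError, ValueError):
    """A simulation or analysis parameter is outside its admissible range."""


class InsufficientDataError(HoofbeatsError, ValueError):
    """Too few events/intervals/ratios to compute the requested quantity."""


class ValidationError(HoofbeatsError, ValueError):
    """Input data violates a structural invariant (ordering, finiteness, ...)."""


class TierNotFoundError(HoofbeatsError, KeyError):
    """The requested TextGrid tier does not exist in the file."""


class FormatError(HoofbeatsError, ValueError):
    """A file could not be parsed as the expected format."""


class SegmentationError(HoofbeatsError, RuntimeError):
    """Motion-cycle segmentation failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PairingError(HoofbeatsError, ValueError):
    """Individuals cannot be paired across gaits; names the offenders."""

    def __init__(self, message: str, unpaired: list[str] | None = None):
        super().__init__(message)
        self.unpaired = unpaired or []


class FittingError(HoofbeatsError, RuntimeError):
    """A statistical model failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


class StratificationError(HoofbeatsError, ValueError):
    """A class is absent from a train/test split."""
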