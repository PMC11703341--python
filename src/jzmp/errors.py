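"""Exception types shared across the package."""


class JzmpError(Exception):
    """Base class for all package errors."""


class InsufficientLandmarksError(JzmpError):
    """Fewer than two fiducial pairs were supplied for a similarity fit."""


class DegenerateConfigurationError(JzmpError):
    """Fiducial geometry does not determine a similarity transform
    (e.g. all source points coincident)."""


class InvalidInputError(JzmpError):
    """Non-finite coordinates or otherwise malformed numeric input."""


class UndefinedDistanceError(JzmpError):
    """Signed distance requested against a tracing with no retained lesion."""


class InvalidMaskError(JzmpError):
    """A lesion mask image is not binary."""


class ParseError(JzmpError):
    """A CSV/JSON input file violates the documented dialect."""


class InsufficientDataError(JzmpError):
    """Too few paired measurements for the requested statistic."""


class UndefinedICCError(JzmpError):
    """Intraclass correlation is undefined (zero total variance)."""


class PairingError(JzmpError):
    """Two exams could not be paired stimulus-by-stimulus."""
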