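"""Exception hierarchy shared across the package."""


class WmcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WmcError, ValueError):
    """Input data violates a structural invariant (bad pH range, too few rows, ...)."""


class ConfigError(WmcError, ValueError):
    """A parameter set is internally inconsistent or incomplete."""


class ChannelMissingError(WmcError):
    """An operation needs a channel that contains no valid samples."""


class SegmentationError(WmcError):
    """Landmark detection produced an inconsistent result."""


class LandmarkNotFoundError(SegmentationError):
    """A landmark criterion was never satisfied anywhere in the recording.

    Carries the landmark name, the criterion that failed, and whatever
    landmarks were already found (``partial``) so callers can emit partial
    reports, e.g. for a capsule retained in the stomach.
    """

    def __init__(self, landmark: str, reason: str, partial: dict | None = None):
        self.landmark = landmark
        self.reason = reason
        self.partial = dict(partial or {})
        super().__init__(f"{landmark} not found: {reason}")
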