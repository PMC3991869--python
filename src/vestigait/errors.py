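"""Exception hierarchy for the vestigait package."""


class VestigaitError(Exception):
    """Base class for all vestigait errors."""


class ParameterError(VestigaitError, ValueError):
    """A parameter violates a documented constraint."""


class FormatError(VestigaitError, ValueError):
    """A sensor file does not conform to the expected CSV layout."""


class SyncNotFoundError(VestigaitError):
    """No synchronization (shake) spike could be located in a recording."""


class NotStationaryError(VestigaitError):
    """A window intended for zero-offset calibration contains movement."""


class TooFewStridesError(VestigaitError):
    """Fewer gait cycles were found than the analysis requires."""


class MalformedCycleError(VestigaitError):
    """Event detection failed for one gait cycle (cycle is skipped)."""


class SegmentTooShortError(VestigaitError):
    """A signal segment is too short for the requested frequency resolution."""


class InputError(VestigaitError, ValueError):
    """Statistical routine received an empty or degenerate sample."""


class ConfigError(VestigaitError, ValueError):
    """A run configuration contains unknown or invalid keys."""
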