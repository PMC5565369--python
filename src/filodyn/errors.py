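"""Exception hierarchy for filodyn."""


class FilodynError(Exception):
    """Base class for all filodyn errors."""


class TrackParseError(FilodynError):
    """A track file record could not be parsed (message names the line)."""


class TrackValidationError(FilodynError):
    """Parsed track data violates a structural invariant."""


class TrackTooShortError(FilodynError):
    """Fewer than two paired frames are available for analysis."""


class NoExtensionError(FilodynError):
    """Extent series has no strictly positive extent; nothing to fit."""


class FitError(FilodynError):
    """A dynamic-model fit produced an invalid (degenerate) model."""


class UnobservableTrackError(FilodynError):
    """A synthetic model yields no observable frame inside the window."""


class NoDomainError(FilodynError):
    """Intensity profile is flat: no expression domain can be measured."""


class ConfigError(FilodynError):
    """Invalid run or generator configuration."""
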