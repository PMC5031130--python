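"""Exception hierarchy for plate import, validation and model fitting."""


class PlateDRCError(Exception):
    """Base class for all package errors."""


class PlateParseError(PlateDRCError):
    """A plate-map or kinetic-export file could not be parsed."""


class PlateValidationError(PlateDRCError):
    """Parsed content violates a plate invariant (duplicate wells, empty plate...)."""


class ExtrapolationError(PlateDRCError):
    """A prediction was requested outside a fitted model's time domain."""


class FitError(PlateDRCError):
    """A model could not be fitted (too few points, non-finite values...)."""


class CutTimeError(PlateDRCError):
    """Cut-time computation is impossible for the given set/parameters."""


class ConfigError(PlateDRCError):
    """A run configuration is missing, contradictory or unreadable."""
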