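"""Exception hierarchy for felscape."""


class FelscapeError(Exception):
    """Base class for all felscape errors."""


class StructureParseError(FelscapeError):
    """A structure file could not be parsed (message names the offending line)."""


class FormatError(FelscapeError):
    """A table or surface file violates the expected on-disk format."""


class ConfigError(FelscapeError):
    """An analysis configuration violates its invariants."""


class EmptyInputError(FelscapeError):
    """An operation received an empty ensemble/series where >= 1 item is required."""
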