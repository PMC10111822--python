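"""Exception hierarchy shared across the package."""


class OutgrowthError(Exception):
    """Base class for all package errors."""


class ValidationError(OutgrowthError, ValueError):
    """Input violates a documented precondition (bad count, range, shape...)."""


class ParseError(OutgrowthError, ValueError):
    """A file could not be parsed; message carries the offending line/field."""


class FixtureError(OutgrowthError):
    """Packaged fixture missing or failed its transcription checksum."""
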