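"""Exception hierarchy shared across the package."""


class NasodxError(Exception):
    """Base class for all package-specific errors."""


class GradeParseError(NasodxError):
    """A grade label could not be interpreted (names the token and row)."""


class ValidationError(NasodxError):
    """Input data violates a schema or domain constraint."""


class MissingGradeError(NasodxError):
    """A rule needed a grade that is still MISSING.

    Raised by the rules engine when a question is evaluated on an exam
    that has not been resolved by consensus aggregation or fallback
    defaults; the message identifies the failing question and slot.
    """


class ConfigError(NasodxError):
    """A configuration value is out of its legal range."""
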