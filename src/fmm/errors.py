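"""Exception hierarchy shared across the pipeline."""


class FMMError(Exception):
    """Base class for all package errors."""


class FormatError(FMMError):
    """A file does not conform to the expected dialect (wrong/missing columns)."""


class ParseError(FMMError):
    """A cell or row could not be parsed; carries row context in the message."""


class ValidationError(FMMError):
    """Data violates a domain invariant (e.g. negative timestamp, NaN sample)."""


class ConfigurationError(FMMError):
    """A configuration value is out of its admissible range."""
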