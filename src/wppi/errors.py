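"""Exception hierarchy shared across the package."""


class WppiError(Exception):
    """Base class for all package errors."""


class ParseError(WppiError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(WppiError, ValueError):
    """Parsed input violates a structural invariant (ragged rows, bad weight...)."""


class ParameterError(WppiError, ValueError):
    """A tuning parameter is outside its admissible range."""
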