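"""Exception hierarchy.

``RibostressError`` is the base for everything this package raises on
purpose.  ``ConfigError`` covers bad run/simulation configuration and maps
to exit code 1 at the command line; ``InputValidationError`` covers
malformed or inconsistent input data and maps to exit code 2.
"""


class RibostressError(Exception):
    """Base class for all errors raised deliberately by ribostress."""


class ConfigError(RibostressError):
    """Invalid configuration (thresholds, unknown keys, bad flag values)."""


class InputValidationError(RibostressError):
    """Input data violates a documented invariant (bad file, bad record)."""


class JoinError(InputValidationError):
    """A required join between tables produced no usable rows."""
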