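"""Exception hierarchy.

Validation problems (bad config, malformed tables, infeasible requests)
raise :class:`RadonShiftError` subclasses; the CLI maps these to exit
code 1 and anything else to exit code 2.
"""


class RadonShiftError(Exception):
    """Base class for all package-raised errors."""


class ConfigurationError(RadonShiftError):
    """A configuration value is invalid; the message names the field."""


class DiaryValidationError(RadonShiftError):
    """An activity diary violates its invariants (e.g. a day far from 24 h)."""


class SchemaError(RadonShiftError):
    """A delimited input file does not match its documented schema."""
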