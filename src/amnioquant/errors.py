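"""Exception hierarchy shared across the pipeline.

Two broad classes matter downstream: configuration/design problems (the run
was set up wrong) and data problems (the inputs are unusable).  The CLI maps
them to distinct exit codes.
"""


class AmnioquantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AmnioquantError, ValueError):
    """A configuration object or CLI argument violates its invariants."""


class DesignError(ConfigurationError):
    """The experimental design is invalid (e.g. no experimental pairs)."""


class InputError(AmnioquantError, ValueError):
    """An input table or value is malformed or insufficient."""


class DegenerateInputError(InputError):
    """Input is formally valid but statistically degenerate (zero spread)."""
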