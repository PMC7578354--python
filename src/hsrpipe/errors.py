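"""Exception hierarchy shared across the pipeline stages."""


class HsrPipeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(HsrPipeError):
    """A synthetic-data specification violates its own invariants."""


class InputError(HsrPipeError):
    """An input table violates a documented contract."""


class ParseError(InputError):
    """A file could not be parsed into the expected table shape."""


class InsufficientOverlapError(InputError):
    """Query/atlas gene intersection fell below the configured floor."""


class UndefinedCorrelationError(HsrPipeError):
    """A correlation is undefined (zero rank variance in a profile)."""


class ConfigError(HsrPipeError):
    """A run configuration is inconsistent or incomplete."""


class DegenerateInputError(HsrPipeError):
    """Data are degenerate for the requested statistic (e.g. zero variance,
    or a viability plate whose baseline signal does not exceed the
    negative-control floor)."""
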