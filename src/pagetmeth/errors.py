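"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class PagetmethError(Exception):
    """Base class for all package errors."""


class ConfigError(PagetmethError):
    """Invalid configuration (bad counts, thresholds outside (0,1), ...)."""


class DataError(PagetmethError):
    """Malformed or inconsistent input data (duplicate ids, ragged rows, ...)."""


class NumericalError(PagetmethError):
    """A numerical procedure failed (rank deficiency, non-convergence, ...)."""
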