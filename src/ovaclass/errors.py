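"""Exception hierarchy shared across the pipeline.

Configuration problems (bad parameter values, impossible requests) and data
problems (malformed files, degenerate inputs) are kept distinct so the CLI
can map them to different exit codes.
"""


class OvaclassError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OvaclassError, ValueError):
    """A parameter or configuration field is invalid; the message names it."""


class ParseError(OvaclassError, ValueError):
    """A delimited-text matrix file is malformed; the message locates the cell."""


class DataError(OvaclassError, ValueError):
    """Input data violates a precondition (e.g. a class with too few samples)."""
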