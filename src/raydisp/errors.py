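"""Exception hierarchy.

Error messages begin with a stable, hyphenated token (``no-boundaries``,
``insufficient-boundaries``, ``empty-profile``, ``channel-mismatch``,
``blob-out-of-bounds``, ``empty-denominator``, ``degenerate-variance``,
``empty-set``) so callers and shell pipelines can match on them.
"""


class RaydispError(Exception):
    """Base class for all raydisp errors."""


class ValidationError(RaydispError, ValueError):
    """Invalid input data or configuration; the message names the field."""


class AnalysisError(RaydispError, RuntimeError):
    """A well-formed input on which the analysis is undefined."""
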