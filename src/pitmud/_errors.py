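"""Exception hierarchy.

Validation problems (bad config, malformed file, broken invariant) raise
:class:`ValidationError`; failures encountered while computing on otherwise
valid data raise :class:`DataError`.  The CLI maps these to exit codes 2
and 3 respectively.
"""


class PitmudError(Exception):
    """Base class for all package errors."""


class ValidationError(PitmudError, ValueError):
    """Input file, configuration, or invariant violation."""


class DataError(PitmudError, ValueError):
    """Runtime data problem (degenerate input to a computation)."""
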