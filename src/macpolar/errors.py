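"""Exception hierarchy.

Every user-facing failure raises one of these; the CLI maps
:class:`ValidationError` (and its subclass :class:`ParseError`) to exit
code 2 and any other :class:`MacpolarError` to exit code 3.
"""


class MacpolarError(Exception):
    """Base class for all errors raised by macpolar."""


class ValidationError(MacpolarError):
    """Invalid inputs: bad shapes, unknown category tokens, broken invariants."""


class ParseError(ValidationError):
    """Malformed on-disk artifact; the message names the offending line."""


class DegenerateDataError(MacpolarError):
    """Data admits no well-defined answer (constant vectors, singleton groups,
    zero-variance regressors)."""
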