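"""Exception hierarchy.

``ValidationError`` marks malformed or contract-violating input (CLI exit
code 2); plain I/O problems raise the builtin ``OSError`` family (exit 3).
"""


class SpanfillError(Exception):
    """Base class for all spanfill errors."""


class ValidationError(SpanfillError):
    """Input violates a format or contract requirement."""
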