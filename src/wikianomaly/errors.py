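"""Exception hierarchy shared across the pipeline.

Exit-code convention for the CLI: input problems map to 1, violated
internal invariants (bugs) map to 2.
"""


class WikianomalyError(Exception):
    """Base class for all package errors."""


class InputFormatError(WikianomalyError, ValueError):
    """A file or field could not be parsed (names the offending row)."""


class IntegrityError(WikianomalyError, ValueError):
    """Inputs are parseable but mutually inconsistent (e.g. conflicting duplicates)."""


class ParameterError(WikianomalyError, ValueError):
    """A caller-supplied parameter violates its documented constraints."""


class ConservationError(WikianomalyError, RuntimeError):
    """An internal count-conservation invariant was violated (a bug guard)."""
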