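"""Exception hierarchy shared across the package.

Input errors (unreadable or malformed files, empty records) are distinct
from usage errors (bad parameter values, wrong call sequence) so the CLI
can map them to different exit codes.
"""


class ArchoriError(Exception):
    """Base class for all package errors."""


class InputError(ArchoriError):
    """A user-supplied file is unreadable, empty or malformed."""


class UsageError(ArchoriError):
    """A parameter value or call is invalid regardless of input data."""
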