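"""Exception hierarchy.

Two broad classes are distinguished so the command-line layer can map them
to distinct exit codes: problems with how the tool was invoked (UsageError)
versus problems with the data it was given (DataError).
"""


class ConsContactsError(Exception):
    """Base class for all errors raised by this package."""


class UsageError(ConsContactsError):
    """The request itself is malformed (bad arguments, wrong model count)."""


class DataError(ConsContactsError):
    """The input data cannot support the requested computation."""


class ScoreUndefinedError(DataError):
    """A score's denominator is empty (e.g. no contacts in either model)."""
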