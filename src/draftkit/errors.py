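"""Exception hierarchy for draftkit.

Every operational failure raises a subclass of :class:`DraftkitError`
so callers (and the CLI) can distinguish bad inputs from bugs.
"""


class DraftkitError(Exception):
    """Base class for all draftkit errors."""


class InvalidParameterError(DraftkitError, ValueError):
    """A parameter is outside its allowed range (e.g. k <= 0)."""


class EmptyInputError(DraftkitError, ValueError):
    """An operation that requires data received none."""


class NoPeakError(DraftkitError):
    """A k-mer histogram has no genomic peak (pure-error, monotone shape)."""


class InvalidModelError(DraftkitError):
    """A peak model is unusable (empty peak interval, non-positive depth)."""


class UndefinedRatioError(DraftkitError):
    """Uniqueness ratio undefined: no valid k-mer positions."""


class UndefinedRateError(DraftkitError):
    """Duplication rate undefined: no aligned pairs to estimate from."""


class MalformedRecordError(DraftkitError, ValueError):
    """A read record is structurally invalid (e.g. empty sequence)."""
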