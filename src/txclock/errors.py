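"""Exception hierarchy for data and format problems.

Plain :class:`ValueError` is used for bad scalar arguments (negative ages,
out-of-range smoothing fractions, ...); the classes here mark problems with
the *content* of input files or serialized models.
"""


class TxClockError(Exception):
    """Base class for txclock-specific errors."""


class FormatError(TxClockError):
    """A file or serialized object does not conform to the expected layout."""


class ConsistencyError(TxClockError):
    """Input records contradict each other (e.g. one sample, two ages)."""
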