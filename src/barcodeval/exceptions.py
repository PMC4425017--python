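"""Exception hierarchy for barcodeval.

Every error raised by the library derives from :class:`BarcodevalError`
so callers can catch package failures without masking programming errors.
"""


class BarcodevalError(Exception):
    """Base class for all barcodeval errors."""


class AlignmentError(BarcodevalError):
    """Sequences violate alignment invariants (unequal lengths, bad residues)."""


class HeaderParseError(BarcodevalError):
    """A FASTA header does not match the configured species/sample pattern."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(BarcodevalError):
    """Input fails a structural invariant (duplicates, infeasible config)."""


class PairingError(BarcodevalError):
    """Region alignments cannot be concatenated because samples do not pair up."""


class ThresholdUndefinedError(BarcodevalError):
    """No intraspecific distances exist, so the 95% threshold cannot be computed."""


class UndefinedDistanceError(BarcodevalError):
    """An operation requires fully defined distances but some pairs are masked."""


class TreeConsistencyError(BarcodevalError):
    """Tree leaves do not match the dataset records, or supports are malformed."""
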