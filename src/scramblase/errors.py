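"""Exception hierarchy for the scramblase assay pipeline.

Exit-code mapping used by the command line interface:
usage errors -> 1, data/validation errors -> 2, numeric failures -> 3.
"""


class ScramblaseError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedFormatError(ScramblaseError):
    """A spectrum file matches none of the known fluorimeter dialects."""


class SpectrumParseError(ScramblaseError):
    """A spectrum file matched a dialect but its data block is malformed."""


class ValidationError(ScramblaseError):
    """Input data (spreadsheet cell, trace invariant, option value) is invalid."""


class DetectionError(ScramblaseError):
    """Dithionite-addition detection failed; a manual addition time may be supplied."""


class FitError(ScramblaseError):
    """A nonlinear fit is under-determined or failed numerically."""
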