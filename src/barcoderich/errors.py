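"""Exception hierarchy for the barcode survey pipeline."""


class BarcodeSurveyError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BarcodeSurveyError):
    """Malformed input file (FASTA, metadata table, newick)."""


class AlignmentError(BarcodeSurveyError):
    """Alignment invariant violated (unequal rows, bad alphabet, ...)."""


class InputError(BarcodeSurveyError):
    """Operation precondition violated by the caller."""


class DegenerateAlignmentError(BarcodeSurveyError):
    """No columns survive complete deletion; distances are undefined."""
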