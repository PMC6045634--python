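"""Exception hierarchy.

Validation errors (bad input files or sequences) derive from
:class:`ValidationError`; errors raised during a computation on valid
inputs derive from :class:`ComputationError`.  The CLI maps the two
branches to distinct exit codes.
"""


class CodonClustersError(Exception):
    """Base class for all package errors."""


class ValidationError(CodonClustersError):
    """Invalid input data or file format."""


class ComputationError(CodonClustersError):
    """Valid inputs, but the requested computation is impossible."""


class FrameError(ValidationError):
    """Sequence length is not a multiple of three."""


class AlphabetError(ValidationError):
    """Sequence contains characters outside the expected alphabet."""


class PrematureStopError(ValidationError):
    """Internal (non-terminal) stop codon in a coding sequence."""


class SequenceTooShortError(ValidationError):
    """Coding sequence shorter than one sliding window."""


class TableCompletenessError(ValidationError):
    """Codon usage table missing one or more sense codons."""


class TableFormatError(ValidationError):
    """Malformed codon usage table (duplicates, bad tokens...)."""


class DegenerateFamilyError(ComputationError):
    """A synonymous-codon family whose frequencies are all zero."""


class ProfileAlignmentError(ComputationError):
    """Two profiles that should share windows do not line up."""


class AnnotationFormatError(ValidationError):
    """Malformed secondary-structure annotation."""

class AnnotationPairingError(ValidationError):
    """Secondary-structure annotation does not match its CDS length."""


class UndefinedStatisticError(ComputationError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class RegressionError(ComputationError):
    """Degenerate regression input (zero predictor variance, n too small)."""


class DomainError(ValidationError):
    """A scalar argument outside its documented domain."""


class ManifestError(ValidationError):
    """Dataset manifest inconsistency (missing files, id cross-references)."""
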