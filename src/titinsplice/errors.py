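"""Exceptions shared across the pipeline modules."""


class TitinspliceError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(TitinspliceError, ValueError):
    """Exon boundaries do not tile the transcript (gap/overlap/out of range)."""


class AmbiguousMatchError(TitinspliceError, ValueError):
    """A transcript exon sequence exactly matches more than one genomic exon."""


class UnmatchedExonError(TitinspliceError, ValueError):
    """A transcript exon has no exact match among the genomic exon sequences."""


class PeptideNotFoundError(TitinspliceError, KeyError):
    """A peptide sequence does not occur in the model protein."""


class NormalizationError(TitinspliceError, ValueError):
    """No constitutive peptide with a usable value in some sample."""


class ConfigurationError(TitinspliceError, ValueError):
    """Invalid or incomplete run configuration."""


class ValidationError(TitinspliceError, ValueError):
    """Malformed input data (negative counts, bad rows, ...)."""
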