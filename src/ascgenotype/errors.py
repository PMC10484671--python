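"""Exception hierarchy for ascgenotype."""


class AscGenotypeError(Exception):
    """Base class for all package-specific errors."""


class EmptyReferenceError(AscGenotypeError):
    """A germline reference (or FASTA file) contained no usable records."""


class DuplicateAlleleError(AscGenotypeError):
    """Two records in a germline reference share the same IUIS name."""


class CoordinateError(AscGenotypeError):
    """Position-based trimming requested without IMGT numbering."""


class SchemaError(AscGenotypeError):
    """A rearrangement table is missing a required column."""


class NotHaplotypableError(AscGenotypeError):
    """The subject is not heterozygous at the requested anchor gene."""


class TranslationError(AscGenotypeError):
    """An allele name could not be translated through the key table."""
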