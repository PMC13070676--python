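"""Exception hierarchy for fragtyper.

All errors raised by the package derive from :class:`FragtyperError` so callers
can catch one base class at workflow boundaries.
"""


class FragtyperError(Exception):
    """Base class for all fragtyper errors."""


class ParseError(FragtyperError):
    """Malformed or empty mutation input."""


class ReferenceMismatchError(FragtyperError):
    """A supplied REF allele contradicts the reference FASTA."""


class UnrepresentableVariantError(FragtyperError):
    """A variant cannot be expressed in anchored VCF form (e.g. anchorless
    event at position 1 of a contig)."""


class ComplexVariantError(FragtyperError):
    """Variant is neither SNV/MNV nor a simple anchored indel after trimming
    (symbolic ALTs, length-changing block substitutions)."""


class MalformedRecordError(FragtyperError):
    """A BAM record whose CIGAR is inconsistent with its sequence."""


class MissingIndexError(FragtyperError):
    """Region queries require an index (.bai/.fai) that was not found."""


class ContigNotFoundError(FragtyperError):
    """A requested contig is absent from the BAM header or FASTA."""
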