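"""Typed error signals shared across the toolkit.

Conditions that a pipeline may legitimately want to catch and handle
(monomorphic loci, unmapped coordinates, unannotated genes) get their own
exception classes rather than sentinel return values, so that "not
computable" is never silently conflated with a zero result.
"""


class AnnokitError(Exception):
    """Base class for all toolkit errors."""


class TableFormatError(AnnokitError):
    """Malformed tabular input (ragged row, empty file, duplicate column)."""


class DuplicateDatasetError(AnnokitError):
    """A (name, version) pair re-registered with a different checksum."""


class UnknownReleaseError(AnnokitError):
    """No manifest exists for the requested release."""


class ToolNotPinnedError(AnnokitError):
    """The release manifest does not pin the requested tool to a dataset."""


class ChecksumMismatchError(AnnokitError):
    """Stored digest does not match the file content."""


class MonomorphicLocusError(AnnokitError):
    """LD is undefined: at least one locus has allele frequency 0 or 1."""


class NoBlockError(AnnokitError):
    """No haplotype block exists on the variant's chromosome."""


class InvalidOffsetMapError(AnnokitError):
    """Liftover map contains overlapping source intervals."""


class UnknownTermError(AnnokitError):
    """An annotation refers to a term absent from the ontology."""


class CrossNamespaceError(AnnokitError):
    """Term similarity requested for terms in different namespaces."""


class UnannotatedObjectError(AnnokitError):
    """Gene-level similarity is undefined: an object has no usable terms."""


class EmptyStudyError(AnnokitError):
    """Enrichment study set is empty after intersection with the corpus."""


class NoEvidenceError(AnnokitError):
    """Prioritization has no usable evidence channel for any candidate."""
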