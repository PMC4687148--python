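"""Identifier conversion and ortholog mapping over versioned tables.

Identifiers are opaque, case-sensitive labels; namespaces (gene symbol,
stable gene/transcript/protein id, organism-specific ids) are just labels
on the table.  A mapping is many-to-many: one source id may map to several
targets and vice versa.  Conversion preserves table order and returns an
empty list for unknown ids — absence in a given data version is data, not
an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import TableFormatError
from .table import Annotator, read_table

HOMOLOGY_CLASSES = ("one2one", "one2many", "many2many")


@dataclass
class MappingTable:
    """Ordered many-to-many (source, target) identifier associations."""

    source_namespace: str
    target_namespace: str
    pairs: list[tuple[str, str]]
    version: str = ""

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise TableFormatError("duplicate (source, target) pair in mapping")
        self._index: dict[str, list[str]] = {}
        for src, tgt in self.pairs:
            self._index.setdefault(src, []).append(tgt)

    def targets(self, identifier: str) -> list[str]:
        return list(self._index.get(identifier, []))

    def reversed(self) -> "MappingTable":
        return MappingTable(
            self.target_namespace,
            self.source_namespace,
            [(t, s) for s, t in self.pairs],
            version=self.version,
        )

    @classmethod
    def from_tsv(
        cls,
        path: Path | str,
        source_namespace: str = "",
        target_namespace: str = "",
        version: str = "",
    ) -> "MappingTable":
        """Load a 2-column TSV (header = namespaces unless given)."""
        table = read_table(path)
        if len(table.columns) < 2:
            raise TableFormatError("mapping table needs >= 2 columns")
        src_col, tgt_col = table.columns[0], table.columns[1]
        pairs = [(row[0], row[1]) for row in table.rows]
        return cls(
            source_namespace or src_col,
            target_namespace or tgt_col,
            pairs,
            version=version,
        )


def convert(ids: Sequence[str], mapping: MappingTable) -> list[list[str]]:
    """Per-id ordered target lists; unknown id -> empty list."""
    return [mapping.targets(i) for i in ids]


@dataclass
class OrthologTable:
    """Pairwise orthology triples (gene_a, gene_b, homology_class).

    The homology class of each triple must be consistent with the pair
    multiplicities in the table: one2one means both genes occur in exactly
    one triple, one2many means exactly one side is repeated, many2many
    means both are.
    """

    organism_a: str
    organism_b: str
    triples: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        deg_a: dict[str, int] = {}
        deg_b: dict[str, int] = {}
        for ga, gb, cls_ in self.triples:
            if cls_ not in HOMOLOGY_CLASSES:
                raise TableFormatError(f"unknown homology class {cls_!r}")
            deg_a[ga] = deg_a.get(ga, 0) + 1
            deg_b[gb] = deg_b.get(gb, 0) + 1
        for ga, gb, cls_ in self.triples:
            expected = _homology_class(deg_a[ga], deg_b[gb])
            if cls_ != expected:
                raise TableFormatError(
                    f"triple ({ga}, {gb}) labelled {cls_!r} but multiplicities "
                    f"imply {expected!r}"
                )

    @classmethod
    def from_tsv(
        cls, path: Path | str, organism_a: str = "", organism_b: str = ""
    ) -> "OrthologTable":
        table = read_table(path)
        if len(table.columns) < 3:
            raise TableFormatError("ortholog table needs 3 columns")
        triples = [(row[0], row[1], row[2]) for row in table.rows]
        return cls(organism_a or table.columns[0],
                   organism_b or table.columns[1], triples)


def _homology_class(deg_a: int, deg_b: int) -> str:
    if deg_a == 1 and deg_b == 1:
        return "one2one"
    if deg_a == 1 or deg_b == 1:
        return "one2many"
    return "many2many"


def map_orthologs(
    gene_ids: Sequence[str],
    table: OrthologTable,
    allowed_classes: Iterable[str] = HOMOLOGY_CLASSES,
    reverse: bool = False,
) -> list[list[str]]:
    """Per-id ortholog lists restricted to the allowed homology classes.

    ``reverse`` maps organism-b genes back to organism a; mapping a gene
    forward and any result back always recovers the original gene.
    """
    allowed = set(allowed_classes)
    if not allowed:
        raise ValueError("allowed_classes must be non-empty")
    unknown = allowed - set(HOMOLOGY_CLASSES)
    if unknown:
        raise ValueError(f"unknown homology classes: {sorted(unknown)}")
    index: dict[str, list[str]] = {}
    for ga, gb, cls_ in table.triples:
        if cls_ not in allowed:
            continue
        if reverse:
            index.setdefault(gb, []).append(ga)
        else:
            index.setdefault(ga, []).append(gb)
    return [list(index.get(g, [])) for g in gene_ids]


def as_annotator(mapping: MappingTable) -> Annotator:
    """Wrap a mapping for :func:`annokit.table.annotate` (1-column key)."""

    def annotator(key: tuple[str, ...]) -> list[tuple[str, ...]]:
        return [(target,) for target in mapping.targets(key[0])]

    return annotator


def ortholog_annotator(
    table: OrthologTable,
    allowed_classes: Iterable[str] = HOMOLOGY_CLASSES,
) -> Annotator:
    """Annotator appending (ortholog, homology_class) per qualifying triple."""
    allowed = set(allowed_classes)
    index: dict[str, list[tuple[str, str]]] = {}
    for ga, gb, cls_ in table.triples:
        if cls_ in allowed:
            index.setdefault(ga, []).append((gb, cls_))

    def annotator(key: tuple[str, ...]) -> list[tuple[str, ...]]:
        return [(gb, cls_) for gb, cls_ in index.get(key[0], [])]

    return annotator


__all__ = [
    "HOMOLOGY_CLASSES",
    "MappingTable",
    "OrthologTable",
    "convert",
    "map_orthologs",
    "as_annotator",
    "ortholog_annotator",
]
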