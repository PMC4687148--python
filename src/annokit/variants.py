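"""SNP-level utilities: LD scores, haplotype-block assignment, interval
overlap, coordinate liftover, and generic versioned-table lookups.

Coordinates are 1-based with fully closed intervals throughout (the
Ensembl convention); readers of 0-based half-open BED input convert on
load.  Strand is carried on features but ignored by overlap queries — the
block-to-gene step of a GWAS annotation pipeline is strand-agnostic.

Linkage disequilibrium is computed from two-locus haplotype counts; all
arithmetic is exact (rational) until the final float conversion, so the
bound properties 0 <= r^2 <= D' <= 1 hold identically rather than up to
rounding.  Estimating haplotypes from genotypes is out of scope: counts
enter from precomputed sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

from .exceptions import (
    InvalidOffsetMapError,
    MonomorphicLocusError,
    NoBlockError,
    TableFormatError,
)
from .table import AnnotationTable, Annotator, read_table


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    id: str = ""
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    start: int
    end: int
    block_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"block {self.block_id}: start > end")


@dataclass(frozen=True)
class GenomicFeature:
    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class TwoLocusCounts:
    """Haplotype counts for allele pairs (A,B), (A,b), (a,B), (a,b)."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        counts = (self.n11, self.n12, self.n21, self.n22)
        if any(c < 0 for c in counts):
            raise ValueError("haplotype counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("total haplotype count must be positive")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


@dataclass(frozen=True)
class LDScores:
    D: float
    Dprime: float
    r2: float


def ld_scores(counts: TwoLocusCounts) -> LDScores:
    """D, D' and r^2 from two-locus haplotype counts.

    With allele frequencies pA = (n11+n12)/n, pB = (n11+n21)/n and
    haplotype frequency p11 = n11/n:

        D  = p11 - pA pB
        D' = |D| / Dmax,  Dmax = min(pA(1-pB), (1-pA)pB)        if D > 0
                          Dmax = min(pA pB, (1-pA)(1-pB))       if D < 0
        r2 = D^2 / (pA(1-pA) pB(1-pB))

    D' is 0 when D = 0.  Both loci must be polymorphic; otherwise LD is
    undefined and :class:`MonomorphicLocusError` is raised.
    """
    n = counts.total
    pA = Fraction(counts.n11 + counts.n12, n)
    pB = Fraction(counts.n11 + counts.n21, n)
    if pA in (0, 1) or pB in (0, 1):
        raise MonomorphicLocusError(
            f"LD undefined for monomorphic locus (pA={float(pA)}, pB={float(pB)})"
        )
    p11 = Fraction(counts.n11, n)
    D = p11 - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        dprime = D / dmax
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        dprime = -D / dmax
    else:
        dprime = Fraction(0)
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDScores(float(D), float(dprime), float(r2))


def assign_block(
    variant: Variant, blocks: Sequence[HaplotypeBlock]
) -> tuple[HaplotypeBlock, int]:
    """Closest haplotype block on the variant's chromosome.

    Distance is 0 for containment, otherwise the distance to the nearer
    block boundary.  Ties go to the block with the lower start coordinate.
    """
    candidates = [b for b in blocks if b.chrom == variant.chrom]
    if not candidates:
        raise NoBlockError(f"no haplotype block on chromosome {variant.chrom}")

    def distance(block: HaplotypeBlock) -> int:
        if block.start <= variant.pos <= block.end:
            return 0
        if variant.pos < block.start:
            return block.start - variant.pos
        return variant.pos - block.end

    best = min(candidates, key=lambda b: (distance(b), b.start))
    return best, distance(best)


def overlap(
    chrom: str, start: int, end: int, features: Sequence[GenomicFeature]
) -> list[GenomicFeature]:
    """Features sharing >= 1 base with [start, end] (1-based inclusive),
    ordered by (start, feature_id).  Adjacency is not overlap."""
    if start > end:
        raise ValueError("query interval start > end")
    hits = [
        f for f in features
        if f.chrom == chrom and f.start <= end and f.end >= start
    ]
    return sorted(hits, key=lambda f: (f.start, f.feature_id))


class OffsetMap:
    """Assembly liftover over non-overlapping source intervals.

    Each interval (chrom, start, end) carries a target chromosome and an
    additive offset; a position inside an interval maps to pos + offset on
    the target chromosome, positions outside any interval are unmapped.
    Overlapping source intervals are rejected at load time.
    """

    def __init__(self, intervals: Sequence[tuple[str, int, int, str, int]]):
        by_chrom: dict[str, list[tuple[int, int, str, int]]] = {}
        for chrom, start, end, target_chrom, offset in intervals:
            if start > end:
                raise InvalidOffsetMapError(
                    f"interval start > end on {chrom}: [{start}, {end}]"
                )
            by_chrom.setdefault(chrom, []).append((start, end, target_chrom, offset))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1, *_), (s2, _e2, *_) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise InvalidOffsetMapError(
                        f"overlapping intervals on {chrom}: "
                        f"[{s1}, {e1}] and starting at {s2}"
                    )
        self._by_chrom = by_chrom

    @classmethod
    def from_tsv(cls, path: Path | str) -> "OffsetMap":
        """5-column TSV: chrom, start, end, target_chrom, offset."""
        table = read_table(path)
        if len(table.columns) < 5:
            raise TableFormatError("offset map needs 5 columns")
        intervals = [
            (row[0], int(row[1]), int(row[2]), row[3], int(row[4]))
            for row in table.rows
        ]
        return cls(intervals)

    def map_position(self, chrom: str, pos: int) -> Optional[tuple[str, int]]:
        """Mapped (chrom, pos), or None when the position is unmapped."""
        for start, end, target_chrom, offset in self._by_chrom.get(chrom, []):
            if start <= pos <= end:
                return target_chrom, pos + offset
        return None


def liftover(
    pos: int, chrom: str, offset_map: OffsetMap
) -> Optional[tuple[str, int]]:
    return offset_map.map_position(chrom, pos)


def read_blocks(path: Path | str, dialect: str = "1-based") -> list[HaplotypeBlock]:
    """Read blocks from TSV (chrom, start, end, block_id).

    ``dialect`` declares the on-disk coordinate convention per file:
    "1-based" fully closed, or "bed" 0-based half-open (converted on load).
    """
    table = read_table(path)
    blocks = []
    for row in table.rows:
        start, end = int(row[1]), int(row[2])
        if dialect == "bed":
            start += 1
        elif dialect != "1-based":
            raise ValueError(f"unknown coordinate dialect {dialect!r}")
        blocks.append(HaplotypeBlock(row[0], start, end, row[3]))
    return blocks


def read_features(path: Path | str, dialect: str = "1-based") -> list[GenomicFeature]:
    """Read features from TSV (feature_id, chrom, start, end[, strand[, kind]])."""
    table = read_table(path)
    features = []
    for row in table.rows:
        start, end = int(row[2]), int(row[3])
        if dialect == "bed":
            start += 1
        elif dialect != "1-based":
            raise ValueError(f"unknown coordinate dialect {dialect!r}")
        strand = row[4] if len(row) > 4 else "."
        kind = row[5] if len(row) > 5 else "gene"
        features.append(GenomicFeature(row[0], row[1], start, end, strand, kind))
    return features


def lookup_annotation(
    data_table: AnnotationTable, key_column: str
) -> tuple[Annotator, list[str]]:
    """Exact-match multi-hit lookup over a versioned annotation table.

    Returns an annotator (for :func:`annokit.table.annotate`) appending all
    non-key columns of the data table, plus the list of those column names.
    This is the generic access path for attribute tables keyed by variant
    id, gene id or protein accession (conservation scores, clinical
    assertions, drug targets, expression calls, ...).
    """
    key_idx = data_table.column_index(key_column)
    value_idx = [i for i in range(len(data_table.columns)) if i != key_idx]
    new_columns = [data_table.columns[i] for i in value_idx]
    index: dict[str, list[tuple[str, ...]]] = {}
    for row in data_table.rows:
        index.setdefault(row[key_idx], []).append(
            tuple(row[i] for i in value_idx)
        )

    def annotator(key: tuple[str, ...]) -> list[tuple[str, ...]]:
        return list(index.get(key[0], []))

    return annotator, new_columns


__all__ = [
    "Variant",
    "HaplotypeBlock",
    "GenomicFeature",
    "TwoLocusCounts",
    "LDScores",
    "ld_scores",
    "assign_block",
    "overlap",
    "OffsetMap",
    "liftover",
    "read_blocks",
    "read_features",
    "lookup_annotation",
]
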