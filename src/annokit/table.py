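"""Tab-separated annotation tables and the append-column pipeline contract.

Every tool in the suite consumes a table with a mandatory header row,
appends its result columns to each row, and expands a row into several
output rows when the annotated entity has multiple hits.  Input cells are
carried through byte-identical — a downstream tool never alters what an
upstream tool wrote, so arbitrary tools can be chained.

Cells are uninterpreted text: there is no type coercion, no quoting
dialect, and TAB is the only delimiter (cells may not contain tabs or
newlines).  Missing values are written as a configurable token, ``NA`` by
default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence, TextIO, Union

from .exceptions import TableFormatError

#: An annotator maps a key tuple to an ordered list of hit tuples.
Annotator = Callable[[tuple[str, ...]], Sequence[tuple[str, ...]]]

Source = Union[str, Path, TextIO]


@dataclass
class AnnotationTable:
    """In-memory tab-separated table: ordered columns, rows of text cells."""

    columns: list[str]
    rows: list[tuple[str, ...]] = field(default_factory=list)
    missing_token: str = "NA"
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise TableFormatError(f"duplicate column names in {self.columns}")
        width = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise TableFormatError(
                    f"row {i} has {len(row)} cells, expected {width}"
                )

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise TableFormatError(f"unknown column {name!r}") from None

    def column(self, name: str) -> list[str]:
        idx = self.column_index(name)
        return [row[idx] for row in self.rows]

    def project(self, names: Sequence[str]) -> "AnnotationTable":
        """Sub-table with only the named columns, row order preserved."""
        idx = [self.column_index(n) for n in names]
        return AnnotationTable(
            list(names),
            [tuple(row[i] for i in idx) for row in self.rows],
            missing_token=self.missing_token,
            comment_prefix=self.comment_prefix,
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.columns == other.columns and self.rows == other.rows


def _open_source(source: Source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def read_table(
    source: Source,
    missing_token: str = "NA",
    comment_prefix: str = "#",
) -> AnnotationTable:
    """Read a TSV with a header line; lines starting with the comment prefix
    are skipped.  Cells are preserved verbatim.

    Raises :class:`TableFormatError` on empty input or on a ragged row,
    naming the offending physical line number.
    """
    handle, owned = _open_source(source)
    try:
        columns: list[str] | None = None
        rows: list[tuple[str, ...]] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if comment_prefix and line.startswith(comment_prefix):
                continue
            cells = line.split("\t")
            if columns is None:
                columns = cells
                continue
            if len(cells) != len(columns):
                raise TableFormatError(
                    f"line {lineno}: expected {len(columns)} cells, got {len(cells)}"
                )
            rows.append(tuple(cells))
        if columns is None:
            raise TableFormatError("empty input: no header line")
        return AnnotationTable(
            columns, rows, missing_token=missing_token, comment_prefix=comment_prefix
        )
    finally:
        if owned:
            handle.close()


def write_table(table: AnnotationTable, sink: Source) -> None:
    """Write the table as plain TSV (header + rows, newline-terminated)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as handle:
            _write(table, handle)
    else:
        _write(table, sink)


def _write(table: AnnotationTable, handle: TextIO) -> None:
    handle.write("\t".join(table.columns) + "\n")
    for row in table.rows:
        handle.write("\t".join(row) + "\n")


def to_text(table: AnnotationTable) -> str:
    buf = io.StringIO()
    _write(table, buf)
    return buf.getvalue()


def annotate(
    table: AnnotationTable,
    key_columns: Sequence[str],
    annotator: Annotator,
    new_columns: Sequence[str],
    drop_unmatched: bool = False,
) -> AnnotationTable:
    """Append ``new_columns`` to every row, expanding multi-hit rows.

    For each input row the annotator is called with the tuple of cells in
    ``key_columns``; every hit tuple it returns produces one output row
    (input cells byte-identical, hit appended, annotator order kept).  A
    row with zero hits is kept once, padded with the missing token, unless
    ``drop_unmatched`` is set.
    """
    key_idx = [table.column_index(c) for c in key_columns]
    width = len(new_columns)
    out_rows: list[tuple[str, ...]] = []
    padding = (table.missing_token,) * width
    for row in table.rows:
        key = tuple(row[i] for i in key_idx)
        hits = list(annotator(key))
        if not hits:
            if not drop_unmatched:
                out_rows.append(row + padding)
            continue
        for hit in hits:
            if len(hit) != width:
                raise TableFormatError(
                    f"annotator returned {len(hit)} cells for key {key!r}, "
                    f"expected {width}"
                )
            out_rows.append(row + tuple(hit))
    return AnnotationTable(
        list(table.columns) + list(new_columns),
        out_rows,
        missing_token=table.missing_token,
        comment_prefix=table.comment_prefix,
    )


def chain(
    table: AnnotationTable,
    steps: Iterable[tuple[Sequence[str], Annotator, Sequence[str]]],
    drop_unmatched: bool = False,
) -> AnnotationTable:
    """Apply a sequence of (key_columns, annotator, new_columns) steps."""
    for key_columns, annotator, new_columns in steps:
        table = annotate(table, key_columns, annotator, new_columns,
                         drop_unmatched=drop_unmatched)
    return table


__all__ = [
    "AnnotationTable",
    "Annotator",
    "read_table",
    "write_table",
    "to_text",
    "annotate",
    "chain",
]
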