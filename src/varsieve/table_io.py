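"""Reading and writing variant tables under a bound schema.

Tables are plain TSV: a header line, one row per line, no quoting (cells
are raw bytes between tabs, as in VCF/Annovar practice). Lines starting
``##`` before the header are treated as a preamble, preserved verbatim
on write. Paths ending ``.gz`` are decompressed/compressed on the fly.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import TableParseError, VarsieveError
from .schema import (FieldSchema, TypedValue, bind_schema, coerce_value,
                     serialize_value)


@dataclass
class VariantRow:
    """One table line: typed cells keyed by field name."""

    cells: dict
    ordinal: int
    source_id: str


@dataclass
class VariantTable:
    """Ordered rows sharing one bound schema, from one input file."""

    schema: FieldSchema
    rows: list = field(default_factory=list)
    source_id: str = ""
    preamble: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[VariantRow]:
        return iter(self.rows)


def source_id_for(path) -> str:
    """Default source identifier: file stem without .gz / one extension."""
    base = os.path.basename(str(path))
    if base.endswith(".gz"):
        base = base[:-3]
    stem, _, _ = base.rpartition(".")
    return stem or base


def _open_read(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _strip_eol(line: str) -> str:
    if line.endswith("\n"):
        line = line[:-1]
    if line.endswith("\r"):
        line = line[:-1]
    return line


def open_table(path, schema: FieldSchema, *, lenient: bool = False,
               source_id: Optional[str] = None):
    """Open a table for streaming.

    Returns ``(bound_schema, preamble, row_iterator)``. The iterator
    yields :class:`VariantRow` lazily, one pass over the file; ragged
    rows raise :class:`~varsieve.errors.TableParseError` with the line
    number.
    """
    sid = source_id if source_id is not None else source_id_for(path)
    fh = _open_read(path)
    preamble = []
    header_line = None
    lineno = 0
    try:
        for line in fh:
            lineno += 1
            line = _strip_eol(line)
            if line.startswith("##"):
                preamble.append(line)
                continue
            header_line = line
            break
    except Exception:
        fh.close()
        raise
    if header_line is None:
        fh.close()
        raise TableParseError(f"{path}: no header line found")
    header = header_line.split("\t")
    try:
        bound = bind_schema(schema, header)
    except VarsieveError:
        fh.close()
        raise
    ncol = len(header)

    def _rows(start_lineno=lineno):
        n = start_lineno
        ordinal = 0
        with fh:
            for line in fh:
                n += 1
                line = _strip_eol(line)
                if not line:
                    continue
                cells = line.split("\t")
                if len(cells) != ncol:
                    raise TableParseError(
                        f"{path}: line {n}: expected {ncol} fields, "
                        f"got {len(cells)}"
                    )
                typed = {
                    fdef.name: coerce_value(raw, fdef, lenient=lenient, row=n)
                    for fdef, raw in zip(bound, cells)
                }
                yield VariantRow(typed, ordinal, sid)
                ordinal += 1

    return bound, preamble, _rows()


def read_table(path, schema: FieldSchema, *, lenient: bool = False,
               source_id: Optional[str] = None) -> VariantTable:
    """Read a whole table into memory. See :func:`open_table`."""
    bound, preamble, rows = open_table(
        path, schema, lenient=lenient, source_id=source_id
    )
    sid = source_id if source_id is not None else source_id_for(path)
    return VariantTable(bound, list(rows), sid, preamble)


def _open_write(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "wb"), encoding="utf-8",
                                newline="\n")
    return open(path, "w", encoding="utf-8", newline="\n")


def write_table(table: VariantTable, path,
                field_order: Optional[Iterable] = None) -> None:
    """Write a table as TSV.

    ``field_order`` selects and orders the output columns (default: all
    fields in schema order). Missing serializes as ``"."``; multi-valued
    cells rejoin on their declared delimiter. Preamble lines are written
    verbatim before the header.
    """
    names = list(field_order) if field_order is not None else table.schema.names
    unknown = [n for n in names if n not in table.schema]
    if unknown:
        raise VarsieveError(
            "unknown field(s) in output order: " + ", ".join(unknown)
        )
    fdefs = [table.schema[n] for n in names]
    with _open_write(path) as out:
        for line in table.preamble:
            out.write(line + "\n")
        out.write("\t".join(names) + "\n")
        for row in table.rows:
            out.write(
                "\t".join(
                    serialize_value(row.cells[f.name], f) for f in fdefs
                )
                + "\n"
            )
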