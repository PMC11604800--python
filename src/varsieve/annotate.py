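"""Joining external key→record annotation tables onto a variant table.

The mechanism behind gene-level catalogs (OMIM-style phenotype tables)
and any user-supplied TSV: records are looked up by exact key match
(surrounding whitespace trimmed) on a chosen table field, and every
non-key source column becomes a new ``<source>.<column>`` field.
A key with several source records yields a multi-valued cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import AnnotationError
from .schema import FieldDef, serialize_scalar
from .table_io import VariantRow, VariantTable, _open_read, _strip_eol

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSource:
    """A loaded annotation table: label, key column, key → records."""

    name: str
    key_column: str
    columns: list            # non-key columns, file order
    records: dict            # key -> ordered list of {column: str}


def load_annotation(path, key_column: str, name: str) -> AnnotationSource:
    """Load a TSV annotation source keyed on ``key_column``.

    Duplicate keys are preserved as ordered record lists (file order);
    a source with zero data rows is valid but logged.
    """
    with _open_read(path) as fh:
        lines = [_strip_eol(l) for l in fh]
    lines = [l for l in lines if l.strip() and not l.startswith("##")]
    if not lines:
        raise AnnotationError(f"{path}: empty annotation file")
    header = lines[0].split("\t")
    if key_column not in header:
        raise AnnotationError(
            f"{path}: key column {key_column!r} not found; "
            f"available: {', '.join(header)}"
        )
    columns = [c for c in header if c != key_column]
    key_idx = header.index(key_column)
    records: dict = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise AnnotationError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(cells)}"
            )
        key = cells[key_idx].strip()
        rec = {c: cells[header.index(c)] for c in columns}
        records.setdefault(key, []).append(rec)
    if not records:
        logger.warning("%s: annotation source has no data rows", path)
    return AnnotationSource(name, key_column, columns, records)


def _key_strings(value) -> list:
    """Trimmed string forms of a cell's value(s) for key lookup."""
    elems = value if isinstance(value, list) else [value]
    return [serialize_scalar(e).strip() for e in elems if e is not None]


def annotate_table(table: VariantTable, source: AnnotationSource,
                   table_key_field: str, multi_join: str = ";") -> VariantTable:
    """Join ``source`` onto ``table`` by ``table_key_field``.

    Adds one field ``<source.name>.<column>`` per non-key source column,
    declared multi-valued on ``multi_join`` so multiple matching records
    concatenate cleanly. A multi-valued key cell matches on any of its
    values, records in key-value order then source-file order. Unmatched
    keys leave the new cells missing. Row count and existing cells are
    untouched.
    """
    if table_key_field not in table.schema:
        raise AnnotationError(
            f"key field {table_key_field!r} not in table schema"
        )
    new_defs = []
    for col in source.columns:
        fname = f"{source.name}.{col}"
        if fname in table.schema:
            raise AnnotationError(
                f"annotation field {fname!r} collides with an existing field"
            )
        new_defs.append(FieldDef(fname, "S", multi_join, required=False))
    schema = table.schema.extended(new_defs)

    out_rows = []
    for row in table.rows:
        cells = dict(row.cells)
        matched = []
        for k in _key_strings(row.cells.get(table_key_field)):
            matched.extend(source.records.get(k, []))
        for col, fdef in zip(source.columns, new_defs):
            if matched:
                cells[fdef.name] = [rec[col] for rec in matched]
            else:
                cells[fdef.name] = None
        out_rows.append(VariantRow(cells, row.ordinal, row.source_id))
    return VariantTable(schema, out_rows, table.source_id, list(table.preamble))
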