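"""Typed field schemas for tab-delimited annotated-variant tables.

An FD (FieldDefinition) file declares, for each column of an input table,
a field name, a one-letter type code — ``S`` (string), ``I`` (integer) or
``D`` (real number) — and an optional single-character delimiter for
fields that may carry several values in one cell (e.g. Annovar's
``Func.refGene`` column, which can hold ``exonic;splicing``).

The schema drives all downstream typing: cells are coerced to Python
``str``/``int``/``float`` scalars (or lists thereof for multi-valued
fields), with ``""`` and ``"."`` treated as missing for every type, the
convention of VCF and of most annotators built on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .errors import BindingError, CoercionError, SchemaError

logger = logging.getLogger(__name__)

#: Cell contents treated as a missing value regardless of declared type.
MISSING_TOKENS = ("", ".")

#: Serialized form of a missing value.
MISSING_OUT = "."

TYPE_CODES = ("S", "I", "D")

Scalar = Union[str, int, float]
#: A typed cell: missing (None), a scalar, or a list of same-typed
#: scalars / missing markers for multi-valued fields.
TypedValue = Union[None, Scalar, list]


@dataclass(frozen=True)
class FieldDef:
    """Declaration of a single table column.

    Parameters
    ----------
    name:
        Field identifier; must match the input header exactly
        (case-sensitive).
    type_code:
        ``"S"`` string, ``"I"`` integer, ``"D"`` real number.
    multi_delimiter:
        Optional single character splitting a cell into an ordered list
        of values. Must not be the tab character.
    required:
        If true, absence of this field from an input header is a binding
        error.
    """

    name: str
    type_code: str
    multi_delimiter: Optional[str] = None
    required: bool = True

    def __post_init__(self) -> None:
        if not self.name or "\t" in self.name:
            raise SchemaError(f"invalid field name {self.name!r}")
        if self.type_code not in TYPE_CODES:
            raise SchemaError(
                f"unknown type code {self.type_code!r} for field {self.name!r}"
            )
        if self.multi_delimiter is not None:
            if len(self.multi_delimiter) != 1 or self.multi_delimiter == "\t":
                raise SchemaError(
                    f"delimiter for field {self.name!r} must be a single "
                    f"non-tab character, got {self.multi_delimiter!r}"
                )


@dataclass(frozen=True)
class FieldSchema:
    """An ordered collection of :class:`FieldDef` with unique names."""

    defs: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "defs", tuple(self.defs))
        seen = set()
        for d in self.defs:
            if d.name in seen:
                raise SchemaError(f"duplicate field name {d.name!r}")
            seen.add(d.name)
        object.__setattr__(self, "_by_name", {d.name: d for d in self.defs})

    def __iter__(self) -> Iterator[FieldDef]:
        return iter(self.defs)

    def __len__(self) -> int:
        return len(self.defs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FieldDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"field {name!r} not in schema") from None

    @property
    def names(self) -> list:
        return [d.name for d in self.defs]

    def extended(self, new_defs) -> "FieldSchema":
        """Schema with ``new_defs`` appended; existing names are kept."""
        extra = [d for d in new_defs if d.name not in self]
        return FieldSchema(self.defs + tuple(extra))


FD_HEADER = ("Name", "Type", "delimiter(req)")


def parse_fd(fd_text: str) -> FieldSchema:
    """Parse FD file text into a :class:`FieldSchema`.

    The dialect is tab-separated with a header line containing at least
    ``Name`` and ``Type`` columns and optionally ``delimiter(req)``; one
    field per subsequent non-blank line, in file order. Unknown extra
    header columns are ignored with a warning.
    """
    lines = fd_text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.strip():
            header_idx = i
            break
    if header_idx is None:
        raise SchemaError("FD file is empty")
    header = lines[header_idx].rstrip("\r").split("\t")
    try:
        name_col = header.index("Name")
        type_col = header.index("Type")
    except ValueError:
        raise SchemaError(
            "FD header must contain 'Name' and 'Type' columns, "
            f"got {header!r}"
        ) from None
    delim_col = header.index("delimiter(req)") if "delimiter(req)" in header else None
    extra = [c for c in header if c not in FD_HEADER]
    if extra:
        logger.warning("ignoring unknown FD columns: %s", ", ".join(extra))

    defs = []
    seen = set()
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        cells = line.split("\t")
        name = cells[name_col] if name_col < len(cells) else ""
        tcode = cells[type_col] if type_col < len(cells) else ""
        delim = ""
        if delim_col is not None and delim_col < len(cells):
            delim = cells[delim_col]
        if name in seen:
            raise SchemaError(f"duplicate field {name!r} at line {lineno}")
        seen.add(name)
        if tcode not in TYPE_CODES:
            raise SchemaError(f"unknown type code {tcode!r} at line {lineno}")
        if len(delim) > 1:
            raise SchemaError(
                f"multi-character delimiter {delim!r} at line {lineno}"
            )
        defs.append(FieldDef(name, tcode, delim or None))
    return FieldSchema(tuple(defs))


def serialize_fd(schema: FieldSchema) -> str:
    """Render a schema back to FD text (inverse of :func:`parse_fd`)."""
    out = ["\t".join(FD_HEADER)]
    for d in schema:
        out.append(f"{d.name}\t{d.type_code}\t{d.multi_delimiter or ''}")
    return "\n".join(out) + "\n"


def _coerce_scalar(piece: str, fdef: FieldDef, lenient: bool,
                   row: Optional[int]) -> Optional[Scalar]:
    if piece in MISSING_TOKENS:
        return None
    if fdef.type_code == "S":
        return piece
    try:
        return int(piece) if fdef.type_code == "I" else float(piece)
    except ValueError:
        if lenient:
            return None
        raise CoercionError(fdef.name, piece, row) from None


def coerce_value(raw: str, fdef: FieldDef, *, lenient: bool = False,
                 row: Optional[int] = None) -> TypedValue:
    """Coerce one raw (tab-free) cell string to its typed value.

    A wholly-missing cell (``""`` or ``"."``) maps to ``None`` even for
    multi-valued fields; otherwise a multi-valued field always yields a
    list, splitting on its delimiter before coercing each piece.

    With ``lenient=True`` an unparseable numeric scalar demotes to
    missing instead of raising :class:`~varsieve.errors.CoercionError`.
    """
    if raw in MISSING_TOKENS:
        return None
    if fdef.multi_delimiter is not None:
        return [
            _coerce_scalar(p, fdef, lenient, row)
            for p in raw.split(fdef.multi_delimiter)
        ]
    return _coerce_scalar(raw, fdef, lenient, row)


def serialize_scalar(value: Optional[Scalar]) -> str:
    if value is None:
        return MISSING_OUT
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal form
    return str(value)


def serialize_value(value: TypedValue, fdef: FieldDef) -> str:
    """Render a typed value back to its cell string (missing → ``"."``)."""
    if value is None:
        return MISSING_OUT
    if isinstance(value, list):
        if fdef.multi_delimiter is None:
            raise SchemaError(
                f"field {fdef.name!r} holds a list but declares no delimiter"
            )
        return fdef.multi_delimiter.join(serialize_scalar(v) for v in value)
    return serialize_scalar(value)


def bind_schema(schema: FieldSchema, header) -> FieldSchema:
    """Bind a declared schema to an input header.

    Returns a *bound* schema with one :class:`FieldDef` per header
    column, in header order: the declared definition where the name
    matches, otherwise an untyped string passthrough (so unknown columns
    survive to output formatting). Declared fields absent from the
    header are dropped unless ``required``, in which case all missing
    names are reported at once.
    """
    header = list(header)
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise BindingError(
            "ambiguous column(s) in header: " + ", ".join(sorted(dupes))
        )
    missing = [d.name for d in schema if d.required and d.name not in header]
    if missing:
        raise BindingError("missing required field(s): " + ", ".join(missing))
    bound = []
    passthrough = []
    for col in header:
        if col in schema:
            bound.append(schema[col])
        else:
            bound.append(FieldDef(col, "S", None, required=False))
            passthrough.append(col)
    if passthrough:
        logger.info(
            "header columns not in schema carried as strings: %s",
            ", ".join(passthrough),
        )
    return FieldSchema(tuple(bound))
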