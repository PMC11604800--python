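"""Exception hierarchy.

Every error raised by the library derives from :class:`VarsieveError`, so
callers (and the command-line driver) can distinguish data/definition
problems from genuine bugs with a single ``except`` clause.
"""


class VarsieveError(Exception):
    """Base class for all varsieve errors."""


class SchemaError(VarsieveError):
    """A field-definition (FD) file is malformed."""


class BindingError(SchemaError):
    """A schema could not be bound to an input table's header."""


class CoercionError(VarsieveError):
    """A cell value could not be parsed as its field's declared type."""

    def __init__(self, field: str, raw: str, row: int | None = None):
        self.field = field
        self.raw = raw
        self.row = row
        where = f" at data row {row}" if row is not None else ""
        super().__init__(
            f"cannot coerce value {raw!r} for field {field!r}{where}"
        )


class TableParseError(VarsieveError):
    """An input table is structurally broken (e.g. a ragged row)."""


class AnnotationError(VarsieveError):
    """An annotation source cannot be loaded or joined."""


class RuleError(VarsieveError):
    """A filtering-rule (FR) file is malformed or fails to bind."""


class FormatSpecError(VarsieveError):
    """An output format specification is malformed."""


class UsageError(VarsieveError):
    """Invalid command-line option combination."""
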