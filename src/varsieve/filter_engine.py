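"""The filtering-rule language: parsing and evaluation.

An FR (FilteringRule) file declares how a variant is uniquely identified
and a list of named rules::

    BuildingPrimarykey: Chr Start End Ref Alt
    FilteringRule:
    (Chr %e 1) | (Chr %e 3) : chr
    (Func.refGene %e exonic) * (ExAC_ALL %lt 0.005) : base
    # chr %int base : set_intersection

The fields named by ``BuildingPrimarykey`` are serialized and joined
with ``:`` to form each variant's primary key — the unit on which set
operations and cross-file comparisons act.

Expression rules combine comparisons with ``*`` (AND, binds tighter) and
``|`` (OR), with brackets for grouping. Comparison operators:

========  =======================================  applies to
``%e``    equal to                                 any type
``%ne``   not equal to                             any type
``%lt``   less than                                I / D
``%le``   less than or equal                       I / D
``%gt``   greater than                             I / D
``%ge``   greater than or equal                    I / D
``%m``    partial match (substring containment)    S
``%nm``   negated partial match                    S
========  =======================================  ==========

Semantics: a missing cell fails *every* comparison, negated forms
included — an unannotated variant never slips through a negative
filter. A multi-valued cell satisfies a comparison iff ANY element
does. Numeric literals are coerced to the field's type; the field is
never coerced to the literal.

Set rules start with ``#`` and combine the key sets of two previously
defined rules with ``%uni`` (union), ``%int`` (intersection) or ``%dif``
(difference). An operand may be qualified as ``rule@source`` (source id
or 1-based input index) for cross-file comparisons; unqualified set
rules operate within each input file separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import RuleError
from .schema import FieldSchema, serialize_value
from .table_io import VariantRow, VariantTable

logger = logging.getLogger(__name__)

COMPARISON_OPS = ("%e", "%ne", "%lt", "%le", "%gt", "%ge", "%m", "%nm")
ORDER_OPS = ("%lt", "%le", "%gt", "%ge")
MATCH_OPS = ("%m", "%nm")
SET_OPS = ("%uni", "%int", "%dif")


# ---------------------------------------------------------------- AST --

@dataclass(frozen=True)
class Comparison:
    field: str
    op: str
    literal: str  # as written in the rule


@dataclass(frozen=True)
class And:
    parts: tuple


@dataclass(frozen=True)
class Or:
    parts: tuple


FilterExpr = Union[Comparison, And, Or]


@dataclass(frozen=True)
class SetRule:
    left: str
    op: str
    right: str
    left_source: Optional[str] = None   # None = same-file scope
    right_source: Optional[str] = None


@dataclass(frozen=True)
class PrimaryKeySpec:
    fields: tuple

    def __post_init__(self) -> None:
        if not self.fields:
            raise RuleError("BuildingPrimarykey must name at least one field")


@dataclass
class RuleSet:
    key_spec: PrimaryKeySpec
    rules: list  # ordered (name, FilterExpr | SetRule)

    @property
    def names(self) -> list:
        return [n for n, _ in self.rules]


# ---------------------------------------------------------- tokenizer --

_PUNCT = "()|*"


def _tokenize(text: str, lineno: int) -> list:
    """Split an expression into punctuation, quoted and bare tokens.

    Quoted literals ``"..."`` permit spaces and punctuation; a doubled
    quote inside stands for a literal quote. Bare tokens end at
    whitespace, punctuation or a quote.
    """
    toks = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in _PUNCT:
            toks.append(("punct", c))
            i += 1
        elif c == '"':
            j = i + 1
            buf = []
            while True:
                if j >= n:
                    raise RuleError(f"line {lineno}: unterminated quote")
                if text[j] == '"':
                    if j + 1 < n and text[j + 1] == '"':
                        buf.append('"')
                        j += 2
                    else:
                        j += 1
                        break
                else:
                    buf.append(text[j])
                    j += 1
            toks.append(("quoted", "".join(buf)))
            i = j
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in _PUNCT \
                    and text[j] != '"':
                j += 1
            toks.append(("bare", text[i:j]))
            i = j
    return toks


class _ExprParser:
    """Recursive-descent parser: ``|`` < ``*`` < brackets."""

    def __init__(self, toks, lineno):
        self.toks = toks
        self.pos = 0
        self.lineno = lineno

    def _err(self, msg):
        raise RuleError(f"line {self.lineno}: {msg}")

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self):
        t = self.peek()
        if t is None:
            self._err("unexpected end of expression")
        self.pos += 1
        return t

    def parse(self) -> FilterExpr:
        expr = self.or_expr()
        if self.peek() is not None:
            kind, val = self.peek()
            if val == ")":
                self._err("unbalanced brackets: extra ')'")
            self._err(f"unexpected token {val!r}")
        return expr

    def or_expr(self) -> FilterExpr:
        parts = [self.and_expr()]
        while self.peek() == ("punct", "|"):
            self.take()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> FilterExpr:
        parts = [self.atom()]
        while self.peek() == ("punct", "*"):
            self.take()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def atom(self) -> FilterExpr:
        t = self.peek()
        if t == ("punct", "("):
            self.take()
            expr = self.or_expr()
            if self.peek() != ("punct", ")"):
                self._err("unbalanced brackets: missing ')'")
            self.take()
            return expr
        return self.comparison()

    def comparison(self) -> Comparison:
        kind, fname = self.take()
        if kind == "punct":
            self._err(f"expected a field name, got {fname!r}")
        kind, op = self.take()
        if op not in COMPARISON_OPS:
            self._err(f"unknown operator token {op!r}")
        kind, lit = self.take()
        if kind == "punct":
            self._err(f"expected a literal, got {lit!r}")
        return Comparison(fname, op, lit)


# ------------------------------------------------------------ FR file --

def _split_rule_name(line: str, lineno: int):
    """Split a rule line at the last ':' outside quotes → (body, name)."""
    in_quote = False
    last = -1
    i = 0
    while i < len(line):
        c = line[i]
        if c == '"':
            in_quote = not in_quote
        elif c == ":" and not in_quote:
            last = i
        i += 1
    if last < 0:
        raise RuleError(f"line {lineno}: rule line must end with ': <name>'")
    body, name = line[:last], line[last + 1:].strip()
    if not name or any(ch.isspace() for ch in name):
        raise RuleError(f"line {lineno}: invalid rule name {name!r}")
    return body, name


def _parse_operand(tok: str):
    """``rule`` or ``rule@source`` → (rule_name, source_or_None)."""
    if "@" in tok:
        name, _, src = tok.partition("@")
        return name, src
    return tok, None


def parse_fr(fr_text: str) -> RuleSet:
    """Parse FR file text into a :class:`RuleSet`.

    Field existence and type compatibility are checked at bind time
    (:func:`bind_ruleset`), not here; this validates grammar, operator
    tokens, bracket balance, name uniqueness and that set rules only
    reference earlier rules.
    """
    key_spec = None
    rules = []
    defined = set()
    in_rules = False
    for lineno, raw in enumerate(fr_text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("BuildingPrimarykey"):
            rest = line[len("BuildingPrimarykey"):].lstrip(":").strip()
            key_spec = PrimaryKeySpec(tuple(rest.split()))
            continue
        if line.startswith("FilteringRule"):
            in_rules = True
            continue
        if not in_rules:
            raise RuleError(
                f"line {lineno}: unexpected content before 'FilteringRule:'"
            )
        body, name = _split_rule_name(line, lineno)
        if name in defined:
            raise RuleError(f"line {lineno}: duplicate rule name {name!r}")
        if body.lstrip().startswith("#"):
            toks = body.lstrip()[1:].split()
            if len(toks) != 3:
                raise RuleError(
                    f"line {lineno}: set rule must be "
                    "'# <rule> <op> <rule> : <name>'"
                )
            ltok, op, rtok = toks
            if op not in SET_OPS:
                raise RuleError(
                    f"line {lineno}: unknown set operator {op!r}"
                )
            lname, lsrc = _parse_operand(ltok)
            rname, rsrc = _parse_operand(rtok)
            for ref in (lname, rname):
                if ref not in defined:
                    raise RuleError(f"line {lineno}: unknown rule {ref!r}")
            if (lsrc is None) != (rsrc is None):
                raise RuleError(
                    f"line {lineno}: cross-file set rule must qualify "
                    "both operands with @source"
                )
            rules.append((name, SetRule(lname, op, rname, lsrc, rsrc)))
        else:
            expr = _ExprParser(_tokenize(body, lineno), lineno).parse()
            rules.append((name, expr))
        defined.add(name)
    if key_spec is None:
        raise RuleError("FR file lacks a 'BuildingPrimarykey' declaration")
    return RuleSet(key_spec, rules)


# ------------------------------------------------------------- binding --

def _coerce_literal(cmp: Comparison, schema: FieldSchema):
    fdef = schema[cmp.field]
    if fdef.type_code == "S":
        return cmp.literal
    try:
        return int(cmp.literal) if fdef.type_code == "I" else float(cmp.literal)
    except ValueError:
        raise RuleError(
            f"literal {cmp.literal!r} is not a valid "
            f"{'integer' if fdef.type_code == 'I' else 'number'} "
            f"for field {cmp.field!r}"
        ) from None


def _bind_expr(expr: FilterExpr, schema: FieldSchema) -> None:
    if isinstance(expr, (And, Or)):
        for p in expr.parts:
            _bind_expr(p, schema)
        return
    cmp = expr
    if cmp.field not in schema:
        raise RuleError(f"unknown field {cmp.field!r} in rule")
    tcode = schema[cmp.field].type_code
    if cmp.op in ORDER_OPS and tcode == "S":
        raise RuleError(
            f"operator {cmp.op} requires a numeric field, "
            f"but {cmp.field!r} is a string"
        )
    if cmp.op in MATCH_OPS and tcode != "S":
        raise RuleError(
            f"operator {cmp.op} requires a string field, "
            f"but {cmp.field!r} is numeric"
        )
    _coerce_literal(cmp, schema)


def bind_ruleset(ruleset: RuleSet, schema: FieldSchema) -> None:
    """Validate a rule set against one table's bound schema."""
    for f in ruleset.key_spec.fields:
        if f not in schema:
            raise RuleError(f"primary-key field {f!r} not in table")
    for name, rule in ruleset.rules:
        if isinstance(rule, SetRule):
            continue
        try:
            _bind_expr(rule, schema)
        except RuleError as e:
            raise RuleError(f"rule {name!r}: {e}") from None


# ---------------------------------------------------------- evaluation --

def _cmp_scalar(value, op: str, lit) -> bool:
    if op == "%e":
        return value == lit
    if op == "%ne":
        return value != lit
    if op == "%lt":
        return value < lit
    if op == "%le":
        return value <= lit
    if op == "%gt":
        return value > lit
    if op == "%ge":
        return value >= lit
    if op == "%m":
        return lit in value
    if op == "%nm":
        return lit not in value
    raise RuleError(f"unknown operator {op!r}")


def eval_comparison(cmp: Comparison, row: VariantRow,
                    schema: FieldSchema) -> bool:
    """Evaluate one comparison on one row.

    Missing → False for every operator. Multi-valued → True iff any
    non-missing element satisfies the comparison.
    """
    value = row.cells.get(cmp.field)
    if value is None:
        return False
    lit = _coerce_literal(cmp, schema)
    elems = value if isinstance(value, list) else [value]
    return any(
        e is not None and _cmp_scalar(e, cmp.op, lit) for e in elems
    )


def eval_expr(expr: FilterExpr, row: VariantRow,
              schema: FieldSchema) -> bool:
    """Evaluate a whole expression tree on one row."""
    if isinstance(expr, And):
        return all(eval_expr(p, row, schema) for p in expr.parts)
    if isinstance(expr, Or):
        return any(eval_expr(p, row, schema) for p in expr.parts)
    return eval_comparison(expr, row, schema)


def build_primary_key(row: VariantRow, spec: PrimaryKeySpec,
                      schema: FieldSchema) -> str:
    """Serialized key-field values joined with ':' (missing → '.')."""
    return ":".join(
        serialize_value(row.cells.get(f), schema[f]) for f in spec.fields
    )


# ------------------------------------------------------- result + sets --

def _as_odict(keys) -> dict:
    """Normalize a key collection to an insertion-ordered key→row dict."""
    if isinstance(keys, dict):
        return keys
    return {k: None for k in keys}


def set_op(left, right, op: str) -> dict:
    """Standard set semantics on ordered key→row mappings.

    Output order: left's insertion order, then (for ``%uni``) right's
    keys not already present. Plain iterables of keys are accepted for
    convenience (rows become None).
    """
    left = _as_odict(left)
    right = _as_odict(right)
    if op == "%int":
        return {k: v for k, v in left.items() if k in right}
    if op == "%dif":
        return {k: v for k, v in left.items() if k not in right}
    if op == "%uni":
        out = dict(left)
        for k, v in right.items():
            if k not in out:
                out[k] = v
        return out
    raise RuleError(f"unknown set operator {op!r}")


@dataclass
class FilterResult:
    """Per-rule ordered key sets with their source rows.

    ``entries[rule][source_id]`` is an insertion-ordered mapping from
    primary key to the matching :class:`VariantRow` (first-match order).
    """

    entries: dict = field(default_factory=dict)
    duplicate_keys: dict = field(default_factory=dict)  # source_id -> count
    rule_order: list = field(default_factory=list)

    def keys(self, rule: str, source_id: Optional[str] = None) -> list:
        by_src = self.entries[rule]
        if source_id is not None:
            return list(by_src.get(source_id, {}))
        out = []
        for od in by_src.values():
            out.extend(od)
        return out

    def count(self, rule: str, source_id: Optional[str] = None) -> int:
        return len(self.keys(rule, source_id))


def _resolve_source(token: str, tables) -> str:
    by_id = {t.source_id for t in tables}
    if token in by_id:
        return token
    if token.isdigit():
        idx = int(token)
        if 1 <= idx <= len(tables):
            return tables[idx - 1].source_id
    raise RuleError(
        f"unknown source {token!r}; inputs are: "
        + ", ".join(t.source_id for t in tables)
    )


def apply_rules(tables, ruleset: RuleSet) -> FilterResult:
    """Evaluate every rule of ``ruleset`` over ``tables``.

    Expression rules are evaluated in a single pass per table, all rules
    simultaneously; each rule's result carries an entry (possibly empty)
    for every input table. Rows whose primary key duplicates an earlier
    row of the same table are excluded from result sets (first occurrence
    wins) and counted in ``duplicate_keys``. Set rules then combine key
    sets in file order: same-file scope per source, cross-file scope by
    key-string equality between the named sources.
    """
    tables = list(tables)
    for t in tables:
        bind_ruleset(ruleset, t.schema)

    expr_rules = [(n, r) for n, r in ruleset.rules
                  if not isinstance(r, SetRule)]
    result = FilterResult(rule_order=list(ruleset.names))
    for name, _ in ruleset.rules:
        result.entries[name] = {}
    for t in tables:
        for name, _ in expr_rules:
            result.entries[name][t.source_id] = {}

    for t in tables:
        seen = set()
        dups = 0
        for row in t.rows:
            key = build_primary_key(row, ruleset.key_spec, t.schema)
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            for name, expr in expr_rules:
                if eval_expr(expr, row, t.schema):
                    result.entries[name][t.source_id][key] = row
        if dups:
            result.duplicate_keys[t.source_id] = dups
            logger.warning(
                "%s: %d row(s) with duplicate primary keys dropped from "
                "result sets", t.source_id, dups,
            )

    source_order = [t.source_id for t in tables]
    for name, rule in ruleset.rules:
        if not isinstance(rule, SetRule):
            continue
        left = result.entries[rule.left]
        right = result.entries[rule.right]
        if rule.left_source is None:
            out = {}
            sids = [s for s in source_order if s in left or s in right]
            for sid in sids:
                out[sid] = set_op(left.get(sid, {}), right.get(sid, {}),
                                  rule.op)
            result.entries[name] = out
        else:
            lsid = _resolve_source(rule.left_source, tables)
            rsid = _resolve_source(rule.right_source, tables)
            lkeys = left.get(lsid, {})
            rkeys = right.get(rsid, {})
            if rule.op == "%uni":
                # rows come from whichever file contributed; left wins ties
                out = {lsid: dict(lkeys)}
                extra = {k: v for k, v in rkeys.items() if k not in lkeys}
                if lsid == rsid:
                    out[lsid].update(extra)
                elif extra:
                    out[rsid] = extra
                result.entries[name] = out
            else:
                result.entries[name] = {lsid: set_op(lkeys, rkeys, rule.op)}
    return result
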