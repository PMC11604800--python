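"""Independent brute-force machinery for checking the filter engine.

Everything here is deliberately naive and separate from the library's
code paths: tables are built as plain typed dicts, expressions as nested
tuples, and evaluation is a direct transcription of the documented
comparison semantics. The engine is then fed the *serialized* table and
the *rendered* rule text, so parser, coercion and evaluator are all
exercised against this oracle.
"""

from __future__ import annotations

import random

# ---------------------------------------------------------------------
# Random typed tables

FIELDS = [
    # (name, type_code, multi_delimiter)
    ("Idx", "I", None),
    ("Chr", "S", None),
    ("Func", "S", ";"),
    ("Gene", "S", None),
    ("AF", "D", None),
    ("DP", "I", None),
    ("Counts", "I", ","),
]

CHR_POOL = ["1", "2", "3", "X"]
FUNC_POOL = ["exonic", "splicing", "intronic", "ncRNA_exonic", "UTR3"]
GENE_POOL = ["BRCA1", "BRCA2", "ABR", "BR", "TP53", "EGFR"]
AF_POOL = [0.0001, 0.003, 0.005, 0.01, 0.2, 0.49]

P_MISSING = 0.15
P_MISSING_ELEM = 0.1


def _maybe_missing(rng, value):
    return None if rng.random() < P_MISSING else value


def random_row(rng: random.Random, idx: int) -> dict:
    func = rng.sample(FUNC_POOL, rng.randint(1, 2))
    if rng.random() < P_MISSING_ELEM:
        func = func + [None]
    counts = [rng.randint(0, 50) for _ in range(rng.randint(1, 3))]
    return {
        "Idx": idx,
        "Chr": _maybe_missing(rng, rng.choice(CHR_POOL)),
        "Func": _maybe_missing(rng, func),
        "Gene": _maybe_missing(rng, rng.choice(GENE_POOL)),
        "AF": _maybe_missing(
            rng, rng.choice(AF_POOL + [round(rng.random() * 0.5, 6)])
        ),
        "DP": _maybe_missing(rng, rng.randint(0, 100)),
        "Counts": _maybe_missing(rng, counts),
    }


def random_table(rng: random.Random, max_rows: int = 200) -> list:
    return [random_row(rng, i) for i in range(rng.randint(0, max_rows))]


def _ser_scalar(v) -> str:
    if v is None:
        return "."
    if isinstance(v, float):
        return repr(v)
    return str(v)


def serialize_rows(rows) -> str:
    """Render typed rows as the TSV text the engine will read."""
    delims = {name: d for name, _, d in FIELDS}
    lines = ["\t".join(name for name, _, _ in FIELDS)]
    for row in rows:
        cells = []
        for name, _, delim in FIELDS:
            v = row[name]
            if v is None:
                cells.append(".")
            elif isinstance(v, list):
                cells.append(delims[name].join(_ser_scalar(e) for e in v))
            else:
                cells.append(_ser_scalar(v))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


FD_TEXT = "Name\tType\tdelimiter(req)\n" + "".join(
    f"{name}\t{tcode}\t{delim or ''}\n" for name, tcode, delim in FIELDS
)

# ---------------------------------------------------------------------
# Random expressions (nested tuples) and their rule-text rendering

_TYPE = {name: tcode for name, tcode, _ in FIELDS}
S_OPS = ["%e", "%ne", "%m", "%nm"]
NUM_OPS = ["%e", "%ne", "%lt", "%le", "%gt", "%ge"]
SUBSTRINGS = ["BR", "exon", "onic", "1", "X", "A", "splic"]


def random_comparison(rng: random.Random) -> tuple:
    name = rng.choice([f for f, _, _ in FIELDS if f != "Idx"])
    tcode = _TYPE[name]
    if tcode == "S":
        op = rng.choice(S_OPS)
        pool = {"Chr": CHR_POOL, "Func": FUNC_POOL, "Gene": GENE_POOL}[name]
        lit = rng.choice(pool + SUBSTRINGS if op in ("%m", "%nm") else pool)
    elif tcode == "I":
        op = rng.choice(NUM_OPS)
        lit = str(rng.randint(0, 60))
    else:
        op = rng.choice(NUM_OPS)
        lit = repr(rng.choice(AF_POOL))
    return ("cmp", name, op, str(lit))


def random_expr(rng: random.Random, depth: int = 4) -> tuple:
    if depth <= 1 or rng.random() < 0.35:
        return random_comparison(rng)
    kind = rng.choice(["and", "or"])
    parts = tuple(
        random_expr(rng, depth - 1) for _ in range(rng.randint(2, 3))
    )
    return (kind, parts)


def render_expr(node) -> str:
    """Minimal-bracket rendering: AND binds tighter than OR."""
    if node[0] == "cmp":
        _, field, op, lit = node
        return f"{field} {op} {lit}"
    sep = " | " if node[0] == "or" else " * "
    parts = []
    for p in node[1]:
        text = render_expr(p)
        if node[0] == "and" and p[0] == "or":
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


# ---------------------------------------------------------------------
# Naive evaluation on the typed rows

def _cmp(value, op, lit, tcode):
    if tcode == "I":
        lit = int(lit)
    elif tcode == "D":
        lit = float(lit)
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
    raise AssertionError(op)


def oracle_eval(node, row: dict) -> bool:
    if node[0] == "and":
        return all(oracle_eval(p, row) for p in node[1])
    if node[0] == "or":
        return any(oracle_eval(p, row) for p in node[1])
    _, field, op, lit = node
    value = row[field]
    if value is None:
        return False
    elems = value if isinstance(value, list) else [value]
    return any(
        e is not None and _cmp(e, op, lit, _TYPE[field]) for e in elems
    )


def oracle_matching_keys(node, rows) -> list:
    """Primary keys (Idx as string) of rows the expression accepts."""
    return [str(r["Idx"]) for r in rows if oracle_eval(node, r)]
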