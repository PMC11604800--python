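"""Output formatting: one projected, renamed TSV per filtering rule.

A format spec is a headerless 1–2 column TSV: ``source_field<TAB>output_name``
(or just ``source_field`` to keep the original name). Its line order
defines output column order. One spec applies to every rule in a run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

from .errors import FormatSpecError
from .filter_engine import FilterResult
from .schema import serialize_value
from .table_io import VariantTable


@dataclass(frozen=True)
class FormatSpec:
    """Ordered (source_field, output_name) projection."""

    entries: tuple

    def __post_init__(self) -> None:
        seen = set()
        for _, out in self.entries:
            if out in seen:
                raise FormatSpecError(f"duplicate output name {out!r}")
            seen.add(out)


def parse_format_spec(text: str) -> FormatSpec:
    """Parse format-spec text; single-column lines keep the field name."""
    entries = []
    seen = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        cells = line.split("\t")
        src = cells[0]
        out = cells[1] if len(cells) > 1 and cells[1] else src
        if out in seen:
            raise FormatSpecError(
                f"line {lineno}: duplicate output name {out!r}"
            )
        seen.add(out)
        entries.append((src, out))
    return FormatSpec(tuple(entries))


SUMMARY_NAME = "summary.tsv"


def render_rule_outputs(result: FilterResult, tables,
                        spec: Optional[FormatSpec], outdir) -> list:
    """Write one TSV per rule per contributing input, plus a summary.

    Files are named ``<source_id>.<rule>.tsv`` and contain the matching
    rows in input order, projected and renamed per ``spec`` (absent spec:
    all fields, original names and order). A rule with an empty result
    still yields a header-only file. ``summary.tsv`` tabulates rule ×
    source row counts. Returns the list of written paths, summary last.
    """
    tables = list(tables)
    by_sid = {t.source_id: t for t in tables}
    if spec is not None:
        for t in tables:
            unknown = [s for s, _ in spec.entries if s not in t.schema]
            if unknown:
                raise FormatSpecError(
                    f"{t.source_id}: format spec names unknown field(s): "
                    + ", ".join(unknown)
                )
    os.makedirs(outdir, exist_ok=True)
    written = []
    summary_rows = []
    for rule in result.rule_order:
        by_src = result.entries[rule]
        for sid in (t.source_id for t in tables):
            if sid not in by_src:
                continue
            table = by_sid[sid]
            if spec is not None:
                pairs = list(spec.entries)
            else:
                pairs = [(n, n) for n in table.schema.names]
            rows = sorted(by_src[sid].values(), key=lambda r: r.ordinal)
            path = os.path.join(outdir, f"{sid}.{rule}.tsv")
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("\t".join(out for _, out in pairs) + "\n")
                for row in rows:
                    fh.write(
                        "\t".join(
                            serialize_value(row.cells[src], table.schema[src])
                            for src, _ in pairs
                        )
                        + "\n"
                    )
            written.append(path)
            summary_rows.append((rule, sid, len(rows)))
    summary_path = os.path.join(outdir, SUMMARY_NAME)
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rule\tsource\tn_rows\n")
        for rule, sid, n in summary_rows:
            fh.write(f"{rule}\t{sid}\t{n}\n")
    written.append(summary_path)
    return written
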