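"""Expansion of VCF-derived genotype columns into per-sample fields.

Annotated variant tables often carry the original VCF columns verbatim,
with per-sample genotype data packed as colon-separated values whose
layout the FORMAT column declares (e.g. ``GT:AD:DP`` / ``0/1:10,5:15``).
This module unpacks them into separate typed fields — ``Sample1.GT``,
``Sample1.AD``, ``Sample1.DP``, ... — so the filtering language can
address genotype, read counts and derived zygosity like any other
annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import TableParseError, VarsieveError
from .schema import FieldDef, coerce_value
from .table_io import VariantRow, VariantTable

#: Types for well-known FORMAT keys; anything else is a plain string.
FORMAT_KEY_DEFS = {
    "GT": ("S", None),
    "FT": ("S", None),
    "DP": ("I", None),
    "GQ": ("I", None),
    "AD": ("I", ","),
    "PL": ("I", ","),
    "VAF": ("D", None),
    "AF": ("D", None),
}


@dataclass
class GenotypeExpansionConfig:
    """Which columns hold the FORMAT string and the per-sample cells."""

    format_field: str
    sample_fields: list
    derive_zygosity: bool = True
    derive_read_counts: bool = True

    def __post_init__(self) -> None:
        if not self.sample_fields:
            raise VarsieveError("sample_fields must be non-empty")


_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))*$")


def zygosity(gt) -> str:
    """Categorize a VCF GT string.

    ``hom_ref`` (all alleles 0), ``hom_alt`` (diploid, equal non-zero),
    ``het`` (diploid, two distinct called alleles), ``missing`` (any
    ``.`` allele), ``other`` (haploid, polyploid, unparseable). Total
    function: never raises.
    """
    if not isinstance(gt, str) or not gt:
        return "other"
    alleles = re.split(r"[/|]", gt)
    if any(a == "." for a in alleles):
        return "missing"
    if not all(a.isdigit() for a in alleles):
        return "other"
    if len(alleles) != 2:
        return "other"
    a, b = alleles
    if a == b:
        return "hom_ref" if a == "0" else "hom_alt"
    return "het"


def _fdef_for_key(sample: str, key: str) -> FieldDef:
    tcode, delim = FORMAT_KEY_DEFS.get(key, ("S", None))
    return FieldDef(f"{sample}.{key}", tcode, delim, required=False)


def detect_genotype_columns(table: VariantTable) -> Optional[GenotypeExpansionConfig]:
    """Best-effort FORMAT/sample column auto-detection.

    Finds a column whose every non-missing cell looks like a FORMAT key
    list starting with GT (``GT`` or ``GT:AD:DP``...); all columns after
    it are taken as samples. Returns None when no such column exists.
    Opt-in only — trailing-column layouts vary across annotator versions.
    """
    key_list = re.compile(r"^GT(:[A-Za-z0-9]+)*$")
    names = table.schema.names
    for i, name in enumerate(names[:-1]):
        cells = [r.cells[name] for r in table.rows]
        vals = [c for c in cells if isinstance(c, str)]
        if vals and all(key_list.match(v) for v in vals):
            return GenotypeExpansionConfig(name, names[i + 1:])
    return None


def expand_genotypes(table: VariantTable, cfg: GenotypeExpansionConfig,
                     *, lenient: bool = False) -> VariantTable:
    """Unpack FORMAT/sample columns into per-sample typed fields.

    For every FORMAT key K observed anywhere in the table and every
    sample s, a field ``s.K`` is added holding that sample's
    corresponding piece, coerced per :data:`FORMAT_KEY_DEFS`. Keys a row
    does not carry (including VCF-legal trailing drops) yield missing.
    Optionally derives ``s.REF_READS``/``s.ALT_READS`` from AD (first
    allele depth / sum of the rest) and ``s.ZYG`` from GT.

    Row count and pre-existing cells are unchanged; running twice with
    the same config is a no-op the second time.
    """
    for name in [cfg.format_field, *cfg.sample_fields]:
        if name not in table.schema:
            raise VarsieveError(f"genotype column {name!r} not in table")

    observed = []  # FORMAT keys in order of first appearance
    seen = set()
    row_keys = []
    for row in table.rows:
        fmt = row.cells.get(cfg.format_field)
        keys = fmt.split(":") if isinstance(fmt, str) else []
        row_keys.append(keys)
        for k in keys:
            if k not in seen:
                seen.add(k)
                observed.append(k)

    new_defs = []
    for s in cfg.sample_fields:
        for k in observed:
            new_defs.append(_fdef_for_key(s, k))
        if cfg.derive_read_counts:
            new_defs.append(FieldDef(f"{s}.REF_READS", "I", None, False))
            new_defs.append(FieldDef(f"{s}.ALT_READS", "I", None, False))
        if cfg.derive_zygosity:
            new_defs.append(FieldDef(f"{s}.ZYG", "S", None, False))
    schema = table.schema.extended(new_defs)

    out_rows = []
    for row, keys in zip(table.rows, row_keys):
        cells = dict(row.cells)
        for s in cfg.sample_fields:
            raw = row.cells.get(s)
            pieces = raw.split(":") if isinstance(raw, str) else []
            if len(pieces) > len(keys):
                if not lenient:
                    raise TableParseError(
                        f"sample {s!r} row {row.ordinal}: cell has "
                        f"{len(pieces)} values for {len(keys)} FORMAT keys"
                    )
                pieces = []
            by_key = dict(zip(keys, pieces))
            for k in observed:
                fdef = schema[f"{s}.{k}"]
                piece = by_key.get(k)
                cells[fdef.name] = (
                    None if piece is None
                    else coerce_value(piece, fdef, lenient=lenient,
                                      row=row.ordinal)
                )
            if cfg.derive_read_counts:
                ad = cells.get(f"{s}.AD")
                ok = isinstance(ad, list) and ad and all(
                    x is not None for x in ad
                )
                cells[f"{s}.REF_READS"] = ad[0] if ok else None
                cells[f"{s}.ALT_READS"] = sum(ad[1:]) if ok else None
            if cfg.derive_zygosity:
                gt = cells.get(f"{s}.GT")
                cells[f"{s}.ZYG"] = (
                    zygosity(gt) if isinstance(gt, str) else "missing"
                )
        out_rows.append(VariantRow(cells, row.ordinal, row.source_id))

    return VariantTable(schema, out_rows, table.source_id, list(table.preamble))
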