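"""Synthetic annotated-variant tables with known ground truth.

Generates Annovar-style ``multianno`` tables — Chr/Start/End/Ref/Alt,
functional annotation, population allele frequency — with the original
VCF columns (CHROM...FORMAT plus sample genotype cells) appended, the
layout produced by running an annotator with the input VCF carried
through. Alongside each table a *ledger* records, for every row, the
facts needed to answer the canned filtering predicates (chromosome
membership, exonic status, allele frequency) by direct construction.

The ledger is computed while the rows are being built, never by running
the filter engine, so engine results can be checked against it as an
independent ground truth.

Not emulated: linkage structure, realistic site-frequency spectra,
indels, multi-allelic sites.
"""

from __future__ import annotations

import argparse
import math
import os
import random
from dataclasses import dataclass, field
from typing import Optional

CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y"]

#: Annovar-style functional categories; first is the exonic class.
FUNC_EXONIC = "exonic"
FUNC_OTHER = ["intronic", "intergenic", "UTR3", "UTR5",
              "ncRNA_intronic", "upstream", "downstream"]
#: Companion value used when an exonic row is multi-valued, the common
#: real-world combination.
FUNC_EXONIC_COMPANION = "splicing"

GENES = ["BRCA1", "BRCA2", "TP53", "EGFR", "KRAS", "PTEN", "APC", "MLH1",
         "MSH2", "ATM", "CHEK2", "PALB2", "RB1", "VHL", "NF1", "CFTR",
         "DMD", "FBN1", "LDLR", "MYH7"]

BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Composition of a generated table.

    Defaults describe a small germline panel: chromosomes drawn
    uniformly, 40% of variants exonic, 10% of allele frequencies
    unreported, frequencies log-uniform on [1e-6, 0.5] (rare variants
    dominate, as in population catalogs), two samples, 60% of called
    genotypes heterozygous, 10% of functional annotations two-valued.
    """

    n_rows: int = 1000
    seed: int = 0
    chrom_weights: Optional[dict] = None  # None = uniform over CHROMS
    frac_exonic: float = 0.4
    p_missing_exac: float = 0.1
    exac_low: float = 1e-6
    exac_high: float = 0.5
    n_samples: int = 2
    het_rate: float = 0.6
    gt_missing_rate: float = 0.02
    multi_value_rate: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.frac_exonic, self.p_missing_exac, self.het_rate,
                  self.gt_missing_rate, self.multi_value_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_rows < 0:
            raise ValueError("n_rows must be non-negative")
        if self.chrom_weights is not None:
            total = sum(self.chrom_weights.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("chrom_weights must sum to 1")


@dataclass(frozen=True)
class LedgerRow:
    key: str
    chrom: str
    funcs: tuple       # all Func.refGene values of the row
    exac: Optional[float]

    @property
    def is_exonic(self) -> bool:
        return FUNC_EXONIC in self.funcs


@dataclass
class Ledger:
    """Ground-truth facts per generated row, in row order."""

    rows: list = field(default_factory=list)

    def keys_chr_in(self, chroms) -> list:
        chroms = set(chroms)
        return [r.key for r in self.rows if r.chrom in chroms]

    def keys_exonic(self) -> list:
        return [r.key for r in self.rows if r.is_exonic]

    def keys_exac_lt(self, c: float) -> list:
        return [r.key for r in self.rows
                if r.exac is not None and r.exac < c]

    def keys_exonic_and_exac_lt(self, c: float) -> list:
        return [r.key for r in self.rows
                if r.is_exonic and r.exac is not None and r.exac < c]

    def to_tsv(self) -> str:
        out = ["key\tchrom\tfuncs\texac"]
        for r in self.rows:
            exac = repr(r.exac) if r.exac is not None else "."
            out.append(f"{r.key}\t{r.chrom}\t{';'.join(r.funcs)}\t{exac}")
        return "\n".join(out) + "\n"


def table_columns(n_samples: int) -> list:
    return (["Chr", "Start", "End", "Ref", "Alt", "Func.refGene",
             "Gene.refGene", "ExAC_ALL", "CHROM", "POS", "ID", "REF",
             "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            + [f"Sample{i + 1}" for i in range(n_samples)])


def _sample_cell(rng: random.Random, spec: FixtureSpec) -> str:
    if rng.random() < spec.gt_missing_rate:
        return "./."
    dp = rng.randint(10, 99)
    r = rng.random()
    if r < spec.het_rate:
        gt = "0/1"
        alt = max(1, min(dp - 1, round(dp * rng.uniform(0.3, 0.7))))
    elif r < spec.het_rate + (1 - spec.het_rate) / 2:
        gt = "1/1"
        alt = dp
    else:
        gt = "0/0"
        alt = 0
    return f"{gt}:{dp - alt},{alt}:{dp}"


def generate_table(spec: FixtureSpec):
    """Build a table as TSV text plus its ground-truth :class:`Ledger`.

    Deterministic given ``spec.seed``: the same spec always yields
    byte-identical text. Primary keys (Chr:Start:End:Ref:Alt) are unique
    by construction (strictly increasing Start).
    """
    rng = random.Random(spec.seed)
    if spec.chrom_weights is None:
        chrom_pop, chrom_w = CHROMS, None
    else:
        chrom_pop = list(spec.chrom_weights)
        chrom_w = [spec.chrom_weights[c] for c in chrom_pop]
    log_lo = math.log10(spec.exac_low)
    log_hi = math.log10(spec.exac_high)

    lines = ["\t".join(table_columns(spec.n_samples))]
    ledger = Ledger()
    pos = 10_000
    for _ in range(spec.n_rows):
        pos += rng.randint(1, 500)
        chrom = (rng.choices(chrom_pop, weights=chrom_w)[0]
                 if chrom_w else rng.choice(chrom_pop))
        ref = rng.choice(BASES)
        alt = rng.choice([b for b in BASES if b != ref])
        if rng.random() < spec.frac_exonic:
            funcs = [FUNC_EXONIC]
            if rng.random() < spec.multi_value_rate:
                funcs.append(FUNC_EXONIC_COMPANION)
        else:
            funcs = [rng.choice(FUNC_OTHER)]
            if rng.random() < spec.multi_value_rate:
                funcs.append(rng.choice(
                    [f for f in FUNC_OTHER if f != funcs[0]]
                ))
        gene = rng.choice(GENES)
        if rng.random() < spec.p_missing_exac:
            exac = None
            exac_cell = "."
        else:
            exac = 10.0 ** rng.uniform(log_lo, log_hi)
            exac_cell = repr(exac)
        qual = round(rng.uniform(30.0, 3000.0), 2)
        dp_info = rng.randint(20, 400)
        samples = [_sample_cell(rng, spec) for _ in range(spec.n_samples)]
        cells = [chrom, str(pos), str(pos), ref, alt, ";".join(funcs),
                 gene, exac_cell, chrom, str(pos), ".", ref, alt,
                 repr(float(qual)), "PASS", f"DP={dp_info}", "GT:AD:DP",
                 *samples]
        lines.append("\t".join(cells))
        key = f"{chrom}:{pos}:{pos}:{ref}:{alt}"
        ledger.rows.append(LedgerRow(key, chrom, tuple(funcs), exac))
    return "\n".join(lines) + "\n", ledger


def generate_fd(n_samples: int = 2) -> str:
    """FD text matching :func:`generate_table`'s column layout."""
    types = {
        "Chr": ("S", ""), "Start": ("I", ""), "End": ("I", ""),
        "Ref": ("S", ""), "Alt": ("S", ""),
        "Func.refGene": ("S", ";"), "Gene.refGene": ("S", ""),
        "ExAC_ALL": ("D", ""), "CHROM": ("S", ""), "POS": ("I", ""),
        "ID": ("S", ""), "REF": ("S", ""), "ALT": ("S", ""),
        "QUAL": ("D", ""), "FILTER": ("S", ""), "INFO": ("S", ""),
        "FORMAT": ("S", ""),
    }
    out = ["Name\tType\tdelimiter(req)"]
    for col in table_columns(n_samples):
        tcode, delim = types.get(col, ("S", ""))
        out.append(f"{col}\t{tcode}\t{delim}")
    return "\n".join(out) + "\n"


#: The worked three-rule scenario: chromosome-1-or-3 variants, rare
#: exonic variants, and their intersection.
FR_EXAMPLE = """\
BuildingPrimarykey: Chr Start End Ref Alt
FilteringRule:
(Chr %e 1) | (Chr %e 3) : chr
(Func.refGene %e exonic) * (ExAC_ALL %lt 0.005) : base
# chr %int base : set_intersection
"""

FORMAT_SPEC_EXAMPLE = """\
Chr\tChromosome
Start\tPosition
Ref
Alt
Func.refGene\tFunction
Gene.refGene\tGene
ExAC_ALL\tExAC_freq
"""


def write_fixture_bundle(spec: FixtureSpec, outdir) -> dict:
    """Write table.tsv, fd.txt, fr_example.txt, format_spec.txt and
    ledger.tsv into ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    table_text, ledger = generate_table(spec)
    paths = {
        "table": os.path.join(outdir, "table.tsv"),
        "fd": os.path.join(outdir, "fd.txt"),
        "fr": os.path.join(outdir, "fr_example.txt"),
        "format_spec": os.path.join(outdir, "format_spec.txt"),
        "ledger": os.path.join(outdir, "ledger.tsv"),
    }
    contents = {
        "table": table_text,
        "fd": generate_fd(spec.n_samples),
        "fr": FR_EXAMPLE,
        "format_spec": FORMAT_SPEC_EXAMPLE,
        "ledger": ledger.to_tsv(),
    }
    for k, path in paths.items():
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(contents[k])
    return paths


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(
        prog="varsieve-fixtures",
        description="Generate a synthetic annotated-variant fixture bundle "
                    "(table, FD, FR, format spec, ground-truth ledger).",
    )
    ap.add_argument("--rows", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--samples", type=int, default=2)
    ap.add_argument("--outdir", required=True)
    args = ap.parse_args(argv)
    spec = FixtureSpec(n_rows=args.rows, seed=args.seed,
                       n_samples=args.samples)
    paths = write_fixture_bundle(spec, args.outdir)
    for k, p in sorted(paths.items()):
        print(f"{k}\t{p}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
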