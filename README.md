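# varsieve

Schema-driven filtering of tab-delimited annotated variant tables.

## The problem

Variant annotators (Annovar, VEP, SnpEff, ...) each emit their own
table-shaped text format, and most filtering tools accept only VCF — so
filtering an *annotated* table usually means ad-hoc awk/pandas scripts.
`varsieve` treats any tab-separated table as a first-class input: a
small **FD (field definition)** file declares each column's name, type
(`S` string, `I` integer, `D` real) and optional multi-value delimiter,
and an **FR (filtering rule)** file expresses filters over those typed
fields without any programming.

It is aimed at anyone triaging germline variant calls — clinical
analysts prioritising rare exonic candidates, cohort analysts comparing
call sets across files — who wants reproducible, declarative filters on
annotator output.

## The rule language

An FR file names the fields whose serialized values, joined with `:`,
form each variant's **primary key** (the unit of set algebra), then
lists named rules:

```
BuildingPrimarykey: Chr Start End Ref Alt
FilteringRule:
(Chr %e 1) | (Chr %e 3) : chr
(Func.refGene %e exonic) * (ExAC_ALL %lt 0.005) : base
# chr %int base : set_intersection
```

Comparisons are `%e`/`%ne` (equality), `%lt %le %gt %ge` (numeric
order), `%m`/`%nm` (substring partial match on strings); `*` is AND,
`|` is OR (`*` binds tighter; brackets override). Lines starting `#`
combine the key sets of earlier rules with `%uni`, `%int`, `%dif` —
within one file, or across input files via `rule@source` operands.
Two semantic rules worth knowing: a **missing** cell (`.` or empty)
fails *every* comparison, negated ones included, so unannotated
variants never slip through a negative filter; and a **multi-valued**
cell (e.g. `exonic;splicing`) satisfies a comparison if *any* element
does.

Around the engine sit a genotype preprocessor (expands VCF
`FORMAT`/sample columns into typed per-sample fields such as
`Sample1.GT`, `Sample1.AD`, derived `REF_READS`/`ALT_READS` and
zygosity), a generic annotation join (TSV key→record sources, e.g. a
gene→phenotype catalog), and an output formatter that writes one
projected, renamed TSV per rule plus a run summary.

## Worked example

Generate a synthetic 1,000-row Annovar-style table (with embedded VCF
genotype columns and a ground-truth ledger), then run the full
pipeline:

```
varsieve-fixtures --rows 1000 --seed 42 --outdir demo
varsieve --in demo/table.tsv --fd demo/fd.txt --fr demo/fr_example.txt \
         --format-spec demo/format_spec.txt \
         --gt-format-field FORMAT --gt-sample-fields Sample1,Sample2 \
         --steps preprocess,filter,format --outdir demo/out
```

The run logs one machine-readable line per stage:

```
INFO	stage	table	read	rows_in=1000	rows_out=1000
INFO	stage	table	preprocess	rows_in=1000	rows_out=1000
INFO	stage	table	filter:chr	rows_in=1000	rows_out=72
INFO	stage	table	filter:base	rows_in=1000	rows_out=242
INFO	stage	table	filter:set_intersection	rows_in=1000	rows_out=14
```

and `demo/out/summary.tsv` tabulates the same counts: of 1,000
variants, 72 lie on chromosome 1 or 3, 242 are exonic with ExAC
frequency below 0.005, and 14 satisfy both. Each rule also gets its own
file, projected through the format spec:

```
$ head -3 demo/out/table.set_intersection.tsv
Chromosome	Position	Ref	Alt	Function	Gene	ExAC_freq
1	76293	T	A	exonic	MYH7	0.0019142790164313164
1	82098	T	A	exonic;splicing	FBN1	7.28792076796399e-05
```

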