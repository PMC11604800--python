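# Methods

## Data model

An input table is an ordered sequence of rows under a **bound schema**:
one typed field per header column. Fields declared in the FD file carry
their declared type (`S`/`I`/`D`) and optional multi-value delimiter;
header columns *not* declared are retained as untyped strings rather
than rejected, so a minimal FD file suffices for any table-shaped
input and undeclared columns still reach the output formatter. Fields
declared but absent from the header are an error only when required.

Cell typing rules:

* `""` and `"."` are missing for every type — the VCF/Annovar
  convention. Missing survives round trips as `"."`.
* A multi-valued field always holds a list (even of one element) when
  non-missing; a scalar field never holds a list.
* Reals serialize via Python's shortest round-tripping `repr`, so
  write→read is the identity on parsed values and a second
  write is byte-identical to the first (the first write may normalise
  textual forms such as trailing zeros).
* Coercion failure is a hard error carrying field, raw value and row
  number; `--lenient` demotes it to missing. The hard default is
  deliberate: silently corrupting a frequency column would invalidate
  every downstream filter.
* Field names and string comparisons are case-sensitive; this is the
  reproducible default.

No quoting is processed in tables (cells are raw bytes between tabs),
`##` preamble lines are preserved, and `.gz` paths are transparent.

## Filtering semantics

The rule grammar is `expr := and_expr ('|' and_expr)*`,
`and_expr := atom ('*' atom)*`, `atom := '(' expr ')' | field op
literal`, with the eight comparison operators listed in the README.
Literals are bare whitespace-delimited tokens or `"..."` quoted (with
`""` for an embedded quote); numeric literals are coerced to the
*field's* type at bind time — the field is never coerced toward the
literal. AND over OR precedence is the conventional choice; worked
examples are fully bracketed either way.

Two deliberate semantic decisions:

* **Missing fails everything.** A missing cell fails `%ne` and `%nm`
  as well as the positive forms. Rationale: a variant with no ExAC
  entry should not pass `ExAC_ALL %ne 0.5` by default; users who want
  "missing or rare" semantics need an explicit is-missing predicate,
  which (like NOT) is future work.
* **Multi-valued cells are existential.** `Func.refGene %e exonic`
  accepts `exonic;splicing` — matching how `;`-joined annotations are
  read in practice.

Primary keys are the `BuildingPrimarykey` fields serialized and joined
with `:`. Duplicate keys within one table keep the first occurrence in
result sets and log a count; set operations assume unique keys.
Expression rules are evaluated for all rules in a single pass per
table; set rules then combine key sets in declaration order, same-file
scope per source, cross-file scope between the two named sources
(rows for `%int`/`%dif` come from the left operand's table; `%uni`
takes each key's row from whichever file contributed it, left winning
ties). Results are insertion-ordered, making every run byte-
deterministic.

## Genotype expansion

The FORMAT and sample columns are user-configured (an opt-in
auto-detector looks for a column whose cells all match `GT(:KEY)*`);
trailing-column layouts differ across annotator versions, so guessing
by default would be fragile. New fields are named `<sample>.<KEY>` —
unambiguous, and directly addressable by the rule language. Known keys
type as GT/FT→S, DP/GQ→I, AD/PL→I-list on `,`, VAF/AF→D; unknown keys
default to S. Derived fields: `REF_READS` = AD[0], `ALT_READS` = sum of
AD[1:] (one integer even for multi-allelic rows), and `ZYG` ∈
{hom_ref, het, hom_alt, missing, other} where any `.` allele is
missing and non-diploid or unparseable calls are `other`. VCF-legal
trailing drops yield missing; a sample cell with more pieces than
FORMAT keys is an error (missing under lenient mode). Expansion is
idempotent and rejoining the pieces in FORMAT order (dropping trailing
missing) reproduces each original cell exactly — a tested invariant.

## Annotation join

Sources are TSV key→record tables; keys match after trimming
surrounding whitespace, with no alias or fuzzy resolution. Every
non-key column becomes `<source>.<column>`, declared multi-valued on
the join character (default `;`, consistent with the multi-value
delimiter convention) so several matching records, or a multi-valued
key cell matching several keys, concatenate deterministically
(key-value order, then source-file order). No positional/interval
joins. Licensed catalogs are not bundled; the test suite uses a
synthetic gene→phenotype table of the same shape.

## Pipeline and parallelism

Stages run in the fixed order preprocess → annotate → filter → format;
any order-respecting subset is selectable, and a run that stops before
filtering writes `<source>.<stage>.tsv` plus a matching FD file so a
later run can resume exactly (tested: staged runs reproduce a one-shot
run byte for byte). The parallelism unit is the input file: per-file
work runs in a thread pool and results are collected in input order
before anything global happens, which makes serial/parallel byte
identity straightforward and tested, at the cost of no within-file
parallelism. A failing input aborts only its own pipeline; other
inputs complete and the process exits non-zero (0 success, 1 usage
error, 2 data error).

## Synthetic data generator

The generator emulates an Annovar-style `multianno` table with the
original VCF columns appended: Chr/Start/End/Ref/Alt, functional class,
gene symbol, ExAC allele frequency, CHROM...FORMAT and per-sample
`GT:AD:DP` cells with internally consistent depths. Defaults, chosen
once as a plausible germline panel: chromosomes uniform over 1–22/X/Y,
40% exonic, 10% of frequencies missing, frequencies log-uniform on
[1e-6, 0.5] so rare variants dominate as in population catalogs, two
samples, 60% of called genotypes heterozygous, 2% missing calls, 10%
of functional annotations two-valued. Start positions strictly
increase, so primary keys are unique by construction.

While building each row the generator records its chromosome,
functional values and frequency in a **ledger**; predicate key lists
(chromosome membership, exonic status, frequency thresholds and their
conjunctions) are answered from the ledger by direct construction,
never by running the filter engine. Engine-vs-ledger agreement is
therefore an independent end-to-end check, not a tautology. The
generator does not attempt realistic site-frequency spectra, linkage,
indels or multi-allelic sites — so passing tests demonstrate correct
mechanics on representative *shapes* of data, not calibrated behaviour
on real cohorts.

## Verification sizes and numerical choices

The test suite checks the worked three-rule scenario on 10,000
generated rows, engine-vs-oracle equivalence on 500 random
(expression, table) pairs (tables ≤ 200 rows, expression depth ≤ 4,
all eight operators, missing and multi-valued cells included), set
algebra on 100 random key-set pairs, and serial-vs-parallel byte
identity on three inputs; `scripts/acceptance.py` recomputes the same
quantities from scratch (200 oracle trials) at any seed. All
comparisons are exact — the toolkit is deterministic text processing;
no tolerances apply anywhere except float parsing itself, which uses
exact binary equality on round-tripped values.

## Known limitations

No NOT operator or is-missing predicate; no regular-expression
matching; no per-family/trio genotype logic; one format spec per run;
key-only matching for cross-file set operations (field values are not
compared); no CSV/Excel dialects or indexed access.
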