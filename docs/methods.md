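# Methods

## The model: annotation-driven unification

varcat treats cohort harmonization as the application of a declarative
rule set (an *annotation schema*) to a stream of raw tabular rows. A
schema is a function from `(file path, header, row)` to an ordered record
of strings; the engine guarantees that under one schema every record from
every file has exactly the same ordered key set, which is what makes the
outputs of different cohorts concatenable and groupable. All values are
strings end to end: varcat is a data-plumbing layer, not a statistics
layer, and coercing types (or coordinates, or allele encodings) silently
is precisely the class of bug it exists to avoid. The only numeric
interpretation anywhere is inside where-clause evaluation, and even there
it is explicit: ordered comparisons require both sides to parse as
decimal numbers, and equality falls back to string comparison when either
side does not.

### Field resolution

Fields are resolved per row, in schema column order, so a later field
(in particular a plugin) may read earlier fields but never reorder them.
This makes evaluation order well defined and keeps file-level parallelism
safe. The six rule kinds are resolved as:

- **static** — the literal.
- **internal** — the first alias present in the header, in alias order
  (first-alias-wins is the tie-break when a header contains several).
  Header matching is case-insensitive after trimming, because MAF dialects
  disagree on casing; output names are used exactly as written in the
  schema.
- **filename / dirname** — a regex with exactly one capture group applied
  to the file's base name or to the *immediate* parent directory name
  (one metadata unit, not a path; `re.search` semantics).
- **mapping** — the source value (found via aliases, like internal) looked
  up in a tab-delimited two-column table with a header. The table is
  loaded and validated when the annotation loads, so a missing file or a
  duplicate key fails fast rather than mid-cohort.
- **plugin** — a registered plugin's `process(context)` result, coerced to
  `str`.

A field that cannot be resolved yields the schema's missing-value
sentinel if optional (the default — heterogeneous cohorts routinely lack
columns) and aborts the file with `path:row` provenance if `required`.
With every field optional, parsing is total: no header/row combination
errors.

### Readers

Dialects are chosen by extension after stripping one `.gz` (gzip is
otherwise transparent): CSV uses RFC 4180 quoting via the standard
`csv` module (quoted fields may embed delimiters, quotes and newlines);
TSV/MAF/VCF are split on tabs with no quoting, which matches how those
files are written in practice. MAF `#` pragmas and VCF `##` metadata are
skipped; the VCF header is the `#CHROM` line with the `#` removed, and
INFO/FORMAT/sample columns ride along as opaque pass-through strings.
Duplicate header names get positional suffixes (`A`, `A.1`, …). Rows
whose field count differs from the header are a hard error with
provenance by default; `skip_bad_rows` demotes them to a counted, logged
skip. There is no silent-truncation mode. Input is strict UTF-8 unless
lossy replacement is requested explicitly.

### Tasks and the parallelism contract

`find_files` walks the tree once, treats any `*.yaml`/`*.yml` whose top
level is a mapping with a `pattern` key as an annotation, and pairs each
remaining file with the nearest-ancestor annotation whose glob patterns
match its name (an annotation with `recursive: false` only governs its
own directory; two matching annotations in one directory is an error,
because precedence between them would be arbitrary). Pairs are emitted in
lexicographic path order, which fixes the global record order for every
other task.

`cat` requires all pairs in a run to resolve to one column list and
otherwise reports a mismatch rather than unioning columns. `group_by`
partitions kept records by a key field (groups sorted by key; a record
whose key is unresolvable lands in the sentinel-labelled group, because
dropping it would break conservation), and `count` tallies records
against an optional single-comparison where clause — the grammar is
deliberately `FIELD OP LITERAL` with no conjunctions; complex filters
belong in downstream tools.

The unit of parallel work is one input file; workers return fully parsed
record lists which are merged in the (already sorted) pair order, and any
grouping or counting happens after the merge. Determinism for any worker
count therefore holds by construction, not by locking. Worker processes
rebuild the plugin registry from the plugin-directory path instead of
receiving pickled plugin objects, so dynamically loaded user plugins work
under any multiprocessing start method.

### The alteration-type classifier

The built-in plugin classifies a `(REF, ALT)` pair by ordered rules:
non-allelic characters (outside `A/C/G/T/N`, case-insensitive, with `-`
valid only standing alone) → UNKNOWN; both sides empty/`-` → UNKNOWN
(the degenerate pair carries no event, and any other assignment would
break swap symmetry); one side empty/`-` → INS or DEL; equal lengths →
SNV (length 1), MNV (length > 1), or UNKNOWN when `REF == ALT`; unequal
lengths → INS/DEL by comparison. Lengths are compared raw — a
VCF-anchored `A → AT` is an INS without trimming the shared base, since
trimming would rewrite the alleles. The function is total and
deterministic, and swapping the arguments maps INS↔DEL while fixing
SNV/MNV/UNKNOWN; the test suite checks this exhaustively over all
~24,000 pairs of strings over `{A,C,G,T,-}` up to length 3 against an
independently coded rule evaluator.

## Tunable parameters

| parameter | where | default | why |
|---|---|---|---|
| `missing_value` | schema | `""` | MAF convention for absent cells; any string allowed |
| `recursive` | schema | `true` | cohorts usually own a whole subtree |
| `format` | schema | `tsv` | one output dialect per schema; no per-run mixing |
| `required` | field def | `false` | heterogeneous cohorts routinely lack columns |
| `workers` / `--cores` | tasks | 1 | parallelism is opt-in; output is invariant to it |
| `skip_bad_rows` | engine/CLI | off | ragged rows abort by default |
| `lenient_where` | tasks/CLI | off | numeric ops on dirty cells abort by default |

## The synthetic-data generator

`varcat.fixtures.generate_cohorts` emulates the input heterogeneity the
tool exists for, not the biology. Per cohort it writes one file per
requested format containing the *study conditions* used throughout the
tests: uniform chromosomes 1–22 + X, uniform positions in 1..10⁸,
alteration types drawn 60% SNV / 10% MNV / 15% INS / 15% DEL (a
simplified somatic-like mix dominated by SNVs), indels VCF-anchored in
TSV/VCF files and dash-encoded in CSV/MAF files, per-dialect header
spellings (MAF conventional names, lowercase CSV), exactly
`round(0.15 × rows)` rows planted as `FILTER=LowQual`, and a
deterministic quarter of files gzip-compressed (members written with a
zeroed timestamp so regeneration is byte-identical). A YAML manifest
records every ground-truth count.

What it does **not** emulate: realistic mutation spectra or hotspots,
reference-genome consistency of alleles, multi-sample VCF genotypes,
structural variants, or malformed real-world files beyond ragged rows.
Passing tests therefore demonstrate correct *parsing, unification,
counting and metadata injection* under realistic format heterogeneity —
not biological validity of any downstream inference.

Problem sizes in the test suite and acceptance script were chosen to
exercise the contracts at comfortable scale: up to 5 cohorts × 1,000 rows
for conservation and parallel-determinism checks, 50 randomized small
cohorts (≤ 60 rows per file) for oracle equivalence, and the exhaustive
classifier table. The engine itself is streaming and has no per-file size
assumptions.

## Numerical and design choices

- **Where-clause numbers** are compared as Python floats after a strict
  parse; `POS == 5.0` matches `5`. Equality with a non-numeric side is
  string equality. This is documented behavior, not coercion.
- **Group keys** sort as strings, so `10 < 9` lexicographically; keys are
  labels, not magnitudes.
- **Degenerate inputs**: an empty data section is an empty stream, not an
  error; an empty run (`cat` over a tree with no matching files) yields
  no lines and a warning; an all-optional schema never errors.
- **One schema, one output format**: an annotation cannot target several
  output formats at once; run `cat --format` to override per run.
- **Annotation identity**: `load → serialize → load` is structural
  identity (source path excepted); mapping-table paths serialize
  absolute so the round trip is location-independent.
- **Header-derived mode**: when `columns` is omitted the input header
  (minus `exclude_columns`) defines the output per file, with
  definition columns substituted in place or appended — useful for
  single-dialect trees; `cat` still insists the resulting columns agree
  across files.

## Known limitations

- No BCF/tabix/bgzf, no Excel, no JSON/TOML schema dialects, no schema
  inheritance, no remote mapping tables.
- No multi-clause where grammar (no AND/OR), no joins across schemas, no
  sorting task.
- No reference-genome validation, indel left-alignment, or genome-build
  liftover; coordinate or allele rewriting would have to be a plugin a
  user writes deliberately.
- Multi-allelic ALT values pass through unsplit; multi-sample VCF sample
  columns are opaque pass-through columns.
- The plugin registry is cached per plugin-directory path within a
  process; editing a plugin file mid-process requires clearing the cache
  (a fresh CLI invocation always sees current code).
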