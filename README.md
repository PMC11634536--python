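# varcat

Cancer-genomics analyses routinely need to pool somatic mutations called by
different projects, and those projects ship their callsets in different
tabular dialects: MAF with its `Chromosome`/`Start_Position`/
`Reference_Allele`/`Tumor_Seq_Allele2` header, VCF with `##` metadata and a
`#CHROM` header, and ad-hoc CSV/TSV exports with whatever column names the
pipeline produced. On top of that, the metadata that identifies a cohort —
dataset name, directory name, file name — lives outside the files
themselves, so aggregating hundreds of cohorts by hand is error-prone.

varcat solves both problems with a small declarative layer. You write one
YAML **annotation file** per cohort (or per tree) that says which files to
read, which output columns to produce, and where each column's value comes
from; varcat then unifies every matching CSV/TSV/MAF/VCF file (plain or
gzipped) into one table with exactly those columns, in that order,
injecting the cohort metadata as ordinary columns. Four streaming tasks
operate on whole directory trees — `find-files`, `cat`, `group-by`,
`count` — and the latter two can run on several worker processes without
changing a single output byte. Anything the declarative rules cannot
express goes through a per-record **plugin**; a built-in plugin classifies
each `(REF, ALT)` pair as SNV, MNV, INS, DEL or UNKNOWN, handling both
VCF-anchored indels (`A → AT`) and MAF dash-encoded ones (`- → T`).

A column's value can come from six kinds of rule:

| kind       | value source                                                    |
|------------|-----------------------------------------------------------------|
| `static`   | a literal (e.g. the dataset name)                               |
| `internal` | the first matching input column from an ordered alias list      |
| `filename` | a regex capture group applied to the file name                  |
| `dirname`  | a regex capture group applied to the parent directory name      |
| `mapping`  | an input value translated through a two-column lookup table     |
| `plugin`   | a registered plugin's `process(context)` result                 |

Columns listed without a rule pass through from the input header,
matched case-insensitively after trimming. Unresolvable optional fields
yield a configurable sentinel (default: empty string); required ones abort
the file with the path and row number. Coordinates are never converted and
alleles are never rewritten — both VCF and MAF pass through as written.

## Worked example

Generate a toy two-cohort tree (the same generator the test suite uses),
then unify and summarize it:

```sh
$ varcat synth -o demo --cohorts 2 --rows 5 --formats tsv,maf --seed 7 --gzip-fraction 0
demo/manifest.yaml

$ varcat cat -i demo --header
CHROM	POS	REF	ALT	FILTER	DATASET	ALT_TYPE	SOURCE_FORMAT
7	20523075	G	T	PASS	cohortA	SNV	maf
13	37149345	A	T	PASS	cohortA	SNV	maf
11	62566680	-	CTC	PASS	cohortA	INS	maf
...
17	43878136	TTG	T	LowQual	cohortB	DEL	tsv
```

Every record has the same eight columns even though the MAF and TSV inputs
disagree on header names and indel encoding: `CHROM..FILTER` are resolved
through alias lists, `DATASET` is injected from the directory name,
`ALT_TYPE` comes from the built-in classifier plugin, and `SOURCE_FORMAT`
is captured from the file name. Grouping and counting use the same parsed
view:

```sh
$ varcat count -i demo -g ALT_TYPE
DEL	2
INS	5
MNV	2
SNV	11
TOTAL	20

$ varcat count -i demo --where 'FILTER == "PASS"' --cores 2
16
```

So this toy tree holds 20 mutations (11 SNVs, 2 MNVs, 5 insertions,
2 deletions), 16 of which pass the caller's filter; `--cores` only changes
wall-clock time, never the numbers. The same operations are available as
library functions (`varcat.cat`, `varcat.group_by`, `varcat.count`,
`varcat.parse_file`) for use inside a pipeline, and `varcat plugin new
NAME` scaffolds a ready-to-edit plugin template.

An annotation file for your own data looks like:

```yaml
pattern: ["*.maf", "*.vcf*"]
format: tsv
columns: [CHROM, POS, REF, ALT, DATASET, ALT_TYPE]
exclude_rows:
  - {field: FILTER, value: LowQual}
annotation:
  - {type: internal, field: CHROM, aliases: [CHROM, Chromosome]}
  - {type: internal, field: POS, aliases: [POS, Start_Position]}
  - {type: internal, field: REF, aliases: [REF, Reference_Allele]}
  - {type: internal, field: ALT, aliases: [ALT, Tumor_Seq_Allele2]}
  - {type: dirname, field: DATASET, regex: '(.*)'}
  - {type: plugin, field: ALT_TYPE, plugin: alteration_type}
```

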