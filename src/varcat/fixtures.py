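"""Deterministic generator of multi-format toy cohorts with a manifest.

Each cohort is one directory holding one synthetic mutation file per
requested format plus an annotation file; a YAML manifest at the root
records ground-truth counts (per file, per cohort, per alteration type,
per FILTER value) so every task and invariant can be tested without any
download.  Regenerating with the same seed reproduces byte-identical
trees (gzip members are written with a zeroed timestamp).

The synthetic mutations are deliberately simple — uniform chromosomes
1..22+X, uniform positions in 1..1e8, alleles drawn to hit all alteration
classes — with the heterogeneity the engine exists for: MAF files use the
conventional ``Chromosome``/``Start_Position``/``Reference_Allele``/
``Tumor_Seq_Allele2`` header, CSV files a lowercase header, and indels
are VCF-anchored in TSV/VCF files but dash-encoded in CSV/MAF files.
A fixed fraction of rows per file (default 0.15, planted exactly) carry
``FILTER=LowQual``; the rest are ``PASS``.
"""

from __future__ import annotations

import gzip
import random
import string
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .errors import FixtureError
from .schema import AnnotationSchema, FieldDefinition, FieldKind, serialize_annotation

__all__ = ["FixtureManifest", "generate_cohorts", "DEFAULT_FORMATS"]

DEFAULT_FORMATS = ("tsv", "csv", "maf", "vcf")
_BASES = "ACGT"
_CHROMS = [str(i) for i in range(1, 23)] + ["X"]
# alteration-type mix: predominantly SNVs, as in somatic callsets
_TYPE_WEIGHTS = (("SNV", 60), ("MNV", 10), ("INS", 15), ("DEL", 15))

ANNOTATION_COLUMNS = (
    "CHROM", "POS", "REF", "ALT", "FILTER", "DATASET", "ALT_TYPE", "SOURCE_FORMAT",
)


@dataclass
class FixtureManifest:
    """Ground truth for one generated cohort tree (paths relative to root)."""

    seed: int
    n_cohorts: int
    rows_per_file: int
    formats: list[str]
    total_rows: int = 0
    lowqual_total: int = 0
    types: dict[str, int] = dc_field(default_factory=dict)
    files: list[dict] = dc_field(default_factory=list)
    cohorts: dict[str, dict] = dc_field(default_factory=dict)
    annotations: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_cohorts": self.n_cohorts,
            "rows_per_file": self.rows_per_file,
            "formats": list(self.formats),
            "total_rows": self.total_rows,
            "lowqual_total": self.lowqual_total,
            "types": dict(self.types),
            "files": list(self.files),
            "cohorts": dict(self.cohorts),
            "annotations": list(self.annotations),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)


def _cohort_name(i: int) -> str:
    if i < 26:
        return f"cohort{string.ascii_uppercase[i]}"
    return f"cohort{i:03d}"


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _make_variant(rng: random.Random) -> dict:
    """One synthetic mutation with both indel encodings precomputed."""
    names = [t for t, _ in _TYPE_WEIGHTS]
    weights = [w for _, w in _TYPE_WEIGHTS]
    vtype = rng.choices(names, weights=weights, k=1)[0]
    chrom = rng.choice(_CHROMS)
    pos = rng.randint(1, 10**8)
    if vtype == "SNV":
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        anchored = dashed = (ref, alt)
    elif vtype == "MNV":
        length = rng.randint(2, 3)
        ref = _random_seq(rng, length)
        alt = "".join(rng.choice([b for b in _BASES if b != c]) for c in ref)
        anchored = dashed = (ref, alt)
    elif vtype == "INS":
        inserted = _random_seq(rng, rng.randint(1, 3))
        anchor = rng.choice(_BASES)
        anchored = (anchor, anchor + inserted)
        dashed = ("-", inserted)
    else:  # DEL
        deleted = _random_seq(rng, rng.randint(1, 3))
        anchor = rng.choice(_BASES)
        anchored = (anchor + deleted, anchor)
        dashed = (deleted, "-")
    return {"type": vtype, "chrom": chrom, "pos": pos,
            "anchored": anchored, "dashed": dashed}


def _render(fmt: str, variants: list[dict], filters: list[str]) -> str:
    lines: list[str] = []
    if fmt == "tsv":
        lines.append("CHROM\tPOS\tREF\tALT\tFILTER")
        for v, f in zip(variants, filters):
            ref, alt = v["anchored"]
            lines.append(f"{v['chrom']}\t{v['pos']}\t{ref}\t{alt}\t{f}")
    elif fmt == "csv":
        lines.append("chrom,pos,ref,alt,filter")
        for v, f in zip(variants, filters):
            ref, alt = v["dashed"]
            lines.append(f"{v['chrom']},{v['pos']},{ref},{alt},{f}")
    elif fmt == "maf":
        lines.append("#version 2.4")
        lines.append(
            "Chromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tFILTER"
        )
        for v, f in zip(variants, filters):
            ref, alt = v["dashed"]
            lines.append(f"{v['chrom']}\t{v['pos']}\t{ref}\t{alt}\t{f}")
    elif fmt == "vcf":
        lines.append("##fileformat=VCFv4.2")
        lines.append("##source=varcat-fixture")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for v, f in zip(variants, filters):
            ref, alt = v["anchored"]
            lines.append(f"{v['chrom']}\t{v['pos']}\t.\t{ref}\t{alt}\t.\t{f}\t.")
    else:
        raise FixtureError(f"unknown fixture format '{fmt}'")
    return "\n".join(lines) + "\n"


def _write(path: Path, text: str, gzipped: bool) -> None:
    if gzipped:
        with open(path, "wb") as raw:
            # mtime=0 and no embedded filename: byte-identical regeneration
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(text.encode("utf-8"))
    else:
        path.write_text(text, encoding="utf-8")


def cohort_annotation(lowqual_excluded: bool = False) -> AnnotationSchema:
    """The annotation shipped with each generated cohort.

    Metadata columns exercise every resolution mechanism the generator can
    reach: INTERNAL aliases across MAF/VCF/lowercase headers, DATASET from
    the directory name, SOURCE_FORMAT from the file name, and the built-in
    alteration-type plugin.
    """
    defs = (
        FieldDefinition("CHROM", FieldKind.INTERNAL, aliases=("CHROM", "Chromosome")),
        FieldDefinition("POS", FieldKind.INTERNAL, aliases=("POS", "Start_Position")),
        FieldDefinition("REF", FieldKind.INTERNAL, aliases=("REF", "Reference_Allele")),
        FieldDefinition("ALT", FieldKind.INTERNAL, aliases=("ALT", "Tumor_Seq_Allele2")),
        FieldDefinition("FILTER", FieldKind.INTERNAL, aliases=("FILTER",)),
        FieldDefinition("DATASET", FieldKind.DIRNAME, regex="(.*)"),
        FieldDefinition("ALT_TYPE", FieldKind.PLUGIN, plugin_name="alteration_type"),
        FieldDefinition("SOURCE_FORMAT", FieldKind.FILENAME, regex=r"muts\.([a-z]+)"),
    )
    exclusions = (("FILTER", "LowQual"),) if lowqual_excluded else ()
    return AnnotationSchema(
        patterns=("muts.*",),
        columns=ANNOTATION_COLUMNS,
        field_defs=defs,
        exclusions=exclusions,
    )


def generate_cohorts(
    out_dir: str | Path,
    n_cohorts: int = 3,
    rows_per_file: int = 100,
    formats: tuple[str, ...] = DEFAULT_FORMATS,
    seed: int = 42,
    gzip_fraction: float = 0.25,
    lowqual_fraction: float = 0.15,
    lowqual_excluded: bool = False,
    force: bool = False,
) -> FixtureManifest:
    """Create *n_cohorts* cohort directories under *out_dir* and return
    the ground-truth manifest (also written as ``manifest.yaml``).

    Each cohort gets one ``muts.<fmt>`` file per format (a deterministic
    quarter of files gzip-compressed by default) and an
    ``annotation.yaml``.  Exactly ``round(lowqual_fraction * rows)`` rows
    per file are planted as ``FILTER=LowQual``.
    """
    if n_cohorts < 1 or rows_per_file < 1:
        raise FixtureError("n_cohorts and rows_per_file must be positive")
    unknown = set(formats) - set(DEFAULT_FORMATS)
    if unknown:
        raise FixtureError(f"unknown format(s) {sorted(unknown)}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FixtureError(f"{out_dir} exists and is not empty (use force to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = FixtureManifest(
        seed=seed, n_cohorts=n_cohorts, rows_per_file=rows_per_file,
        formats=list(formats),
    )
    manifest.types = {t: 0 for t, _ in _TYPE_WEIGHTS}
    k_lowqual = round(lowqual_fraction * rows_per_file)
    annotation_text = serialize_annotation(cohort_annotation(lowqual_excluded))

    for ci in range(n_cohorts):
        cohort = _cohort_name(ci)
        cdir = out_dir / cohort
        cdir.mkdir(exist_ok=True)
        ann_rel = f"{cohort}/annotation.yaml"
        (out_dir / ann_rel).write_text(annotation_text, encoding="utf-8")
        manifest.annotations.append(ann_rel)
        cohort_entry = {"rows": 0, "lowqual": 0,
                        "types": {t: 0 for t, _ in _TYPE_WEIGHTS}}
        for fmt in formats:
            rng = random.Random(f"{seed}|{cohort}|{fmt}")
            variants = [_make_variant(rng) for _ in range(rows_per_file)]
            low_idx = set(rng.sample(range(rows_per_file), k_lowqual))
            filters = ["LowQual" if i in low_idx else "PASS"
                       for i in range(rows_per_file)]
            gz = random.Random(f"{seed}|gz|{cohort}|{fmt}").random() < gzip_fraction
            fname = f"muts.{fmt}" + (".gz" if gz else "")
            _write(cdir / fname, _render(fmt, variants, filters), gz)

            type_counts = {t: 0 for t, _ in _TYPE_WEIGHTS}
            for v in variants:
                type_counts[v["type"]] += 1
            manifest.files.append({
                "path": f"{cohort}/{fname}", "cohort": cohort, "format": fmt,
                "rows": rows_per_file, "gzip": gz, "lowqual": k_lowqual,
                "types": type_counts,
            })
            cohort_entry["rows"] += rows_per_file
            cohort_entry["lowqual"] += k_lowqual
            for t, n in type_counts.items():
                cohort_entry["types"][t] += n
                manifest.types[t] += n
            manifest.total_rows += rows_per_file
            manifest.lowqual_total += k_lowqual
        manifest.cohorts[cohort] = cohort_entry

    manifest.save(out_dir / "manifest.yaml")
    return manifest
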