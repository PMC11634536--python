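"""Deliberately naive reference implementations used as oracles.

Everything here reads whole files into memory and loops over fields with
plain ifs — no streaming, no shared code with the engine's parse path.
Only the schema dataclasses (type definitions) and the public classifier
function are imported; the transformation logic is reimplemented from
the documented semantics.
"""

from __future__ import annotations

import csv
import gzip
import io
import re
from pathlib import Path

from varcat.plugins import classify_alteration
from varcat.schema import AnnotationSchema, FieldKind


def _norm(s: str) -> str:
    return s.strip().casefold()


def _read_text(path) -> str:
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return fh.read()
    with open(path, encoding="utf-8") as fh:
        return fh.read()


def _dedupe(names):
    out, seen = [], {}
    for raw in names:
        n = raw.strip()
        k = n.casefold()
        c = seen.get(k, 0)
        seen[k] = c + 1
        out.append(n if c == 0 else f"{n}.{c}")
    return out


def naive_read(path) -> tuple[list[str], list[list[str]]]:
    """Whole-file header + rows for one input file, by extension."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    text = _read_text(path)
    if ext == ".csv":
        rows = [r for r in csv.reader(io.StringIO(text)) if any(c.strip() for c in r)]
        return _dedupe(rows[0]), rows[1:]
    lines = [ln for ln in text.split("\n") if ln.strip()]
    if ext == ".vcf":
        body = [ln for ln in lines if not ln.startswith("##")]
        header_line = next(ln for ln in body if ln.startswith("#CHROM"))
        data = [ln for ln in body if not ln.startswith("#CHROM")]
        return (_dedupe(header_line.lstrip("#").split("\t")),
                [ln.split("\t") for ln in data])
    if ext == ".maf":
        lines = [ln for ln in lines if not ln.startswith("#")]
    return _dedupe(lines[0].split("\t")), [ln.split("\t") for ln in lines[1:]]


def naive_parse_file(path, schema: AnnotationSchema) -> list[dict]:
    """Reference for parse_file: list of output-value dicts, kept rows only."""
    header, rows = naive_read(path)
    hnorm = [_norm(h) for h in header]

    def cell(row, name):
        key = _norm(name)
        for i, h in enumerate(hnorm):
            if h == key and i < len(row):
                return row[i]
        return None

    if schema.columns is not None:
        cols = list(schema.columns)
    else:
        excl = {_norm(e) for e in schema.excluded_columns}
        cols = [h for h in header if _norm(h) not in excl]
        for d in schema.field_defs:
            if _norm(d.name) in [_norm(c) for c in cols]:
                cols = [d.name if _norm(c) == _norm(d.name) else c for c in cols]
            else:
                cols.append(d.name)

    defs = {_norm(d.name): d for d in schema.field_defs}
    file_name = Path(path).name
    dir_name = Path(path).resolve().parent.name
    sentinel = schema.missing_sentinel
    out = []
    for row in rows:
        if len(row) != len(header):
            raise ValueError(f"ragged row in {path}")
        rec: dict[str, str] = {}
        for col in cols:
            d = defs.get(_norm(col))
            if d is None:
                v = cell(row, col)
                rec[col] = sentinel if v is None else v
            elif d.kind is FieldKind.STATIC:
                rec[col] = d.value
            elif d.kind is FieldKind.INTERNAL:
                v = None
                for alias in d.aliases:
                    v = cell(row, alias)
                    if v is not None:
                        break
                rec[col] = sentinel if v is None else v
            elif d.kind in (FieldKind.FILENAME, FieldKind.DIRNAME):
                subject = file_name if d.kind is FieldKind.FILENAME else dir_name
                m = re.search(d.regex, subject)
                rec[col] = m.group(1) if m else sentinel
            elif d.kind is FieldKind.MAPPING:
                key = None
                for alias in d.aliases:
                    key = cell(row, alias)
                    if key is not None:
                        break
                rec[col] = d.mapping.get(key, sentinel) if key is not None else sentinel
            elif d.kind is FieldKind.PLUGIN:
                if d.plugin_name != "alteration_type":
                    rec[col] = sentinel
                else:
                    ref = rec.get("REF") or cell(row, "REF") or cell(row, "Reference_Allele")
                    alt = rec.get("ALT") or cell(row, "ALT") or cell(row, "Tumor_Seq_Allele2")
                    rec[col] = (classify_alteration(ref, alt)
                                if ref is not None and alt is not None else "UNKNOWN")
        if any(rec.get(f) == v for f, v in schema.exclusions):
            continue
        out.append(rec)
    return out


def naive_filter_count(records: list[dict], field: str, op: str, literal: str) -> int:
    """Brute-force count of records matching one comparison."""
    def num(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return None

    n = 0
    for rec in records:
        left = rec.get(field, "")
        ln, rn = num(left), num(literal)
        if op in ("<", "<=", ">", ">="):
            if ln is None or rn is None:
                raise ValueError("non-numeric ordered comparison")
            ok = {"<": ln < rn, "<=": ln <= rn, ">": ln > rn, ">=": ln >= rn}[op]
        elif op == "==":
            ok = (ln == rn) if (ln is not None and rn is not None) else (left == literal)
        else:
            ok = not ((ln == rn) if (ln is not None and rn is not None) else (left == literal))
        n += ok
    return n


def naive_group(records: list[dict], key_field: str, sentinel: str = "") -> dict[str, int]:
    groups: dict[str, int] = {}
    for rec in records:
        key = rec.get(key_field, sentinel)
        groups[key] = groups.get(key, 0) + 1
    return groups
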