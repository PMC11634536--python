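"""Streaming readers for CSV/TSV/MAF/VCF files, plain or gzipped.

All four formats are reduced to the same shape: an ordered header followed
by a stream of :class:`RawRow` values.  The readers are deliberately
format-unifying rather than format-semantic — VCF INFO/FORMAT/sample
columns are carried as opaque strings, multi-allelic ALT values pass
through unsplit, and coordinates are never converted (both VCF and MAF are
1-based as written; any adjustment belongs in an explicit plugin).

Dialects are chosen by extension after stripping one optional ``.gz``:

========  =========  ================  ==============================
ext       delimiter  comments skipped  header rule
========  =========  ================  ==============================
.csv      ,          —                 first line (RFC 4180 quoting)
.tsv/.txt tab        —                 first line
.maf      tab        lines with "#"    first non-comment line
.vcf      tab        lines with "##"   the line starting "#CHROM"
========  =========  ================  ==============================
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, TextIO

from .errors import DecodeError, HeaderError, UnsupportedFormatError

__all__ = ["Dialect", "RawRow", "detect_dialect", "read_header", "iter_rows", "read_table"]


@dataclass(frozen=True)
class Dialect:
    """Per-format reading rules."""

    format_tag: str  # CSV | TSV | MAF | VCF
    delimiter: str
    comment_prefixes: tuple[str, ...]
    header_rule: str  # "first" or "vcf-chrom"
    gzipped: bool = False


@dataclass
class RawRow:
    """One data line, split on the dialect delimiter."""

    values: list[str]
    row_number: int  # 1-based among data rows
    byte_line: str


_EXT_DIALECTS = {
    ".csv": ("CSV", ",", (), "first"),
    ".tsv": ("TSV", "\t", (), "first"),
    ".txt": ("TSV", "\t", (), "first"),
    ".maf": ("MAF", "\t", ("#",), "first"),
    ".vcf": ("VCF", "\t", ("##",), "vcf-chrom"),
}


def detect_dialect(path: str | Path) -> Dialect:
    """Choose a dialect from the file extension (one trailing ``.gz`` is
    stripped first).  Unrecognized extensions raise
    :class:`UnsupportedFormatError`."""
    name = Path(path).name
    gzipped = name.endswith(".gz")
    if gzipped:
        name = name[: -len(".gz")]
    ext = Path(name).suffix.lower()
    try:
        tag, delim, comments, rule = _EXT_DIALECTS[ext]
    except KeyError:
        raise UnsupportedFormatError(
            f"unsupported input format '{ext or name}' for {path}"
        ) from None
    return Dialect(tag, delim, comments, rule, gzipped)


def _open_text(path: str | Path, dialect: Dialect, lossy: bool = False) -> TextIO:
    errors = "replace" if lossy else "strict"
    if dialect.gzipped:
        return gzip.open(path, "rt", encoding="utf-8", errors=errors, newline="")
    return open(path, encoding="utf-8", errors=errors, newline="")


def _dedupe(names: list[str]) -> list[str]:
    """Trim names; disambiguate duplicates positionally (NAME, NAME.1, ...)."""
    out: list[str] = []
    counts: dict[str, int] = {}
    for raw in names:
        name = raw.strip()
        key = name.casefold()
        n = counts.get(key, 0)
        counts[key] = n + 1
        out.append(name if n == 0 else f"{name}.{n}")
    return out


def _is_comment(line: str, dialect: Dialect) -> bool:
    if dialect.header_rule == "vcf-chrom":
        # "##" metadata only; the "#CHROM" line is the header, and VCF data
        # lines never start with "#"
        return line.startswith("##")
    return any(line.startswith(p) for p in dialect.comment_prefixes)


def _header_from_line(line: str, dialect: Dialect) -> list[str] | None:
    if dialect.header_rule == "vcf-chrom":
        if line.startswith("#CHROM"):
            return _dedupe(line.lstrip("#").rstrip("\r\n").split(dialect.delimiter))
        return None
    return _dedupe(line.rstrip("\r\n").split(dialect.delimiter))


class _Recorder:
    """Iterator wrapper remembering the raw text consumed since last reset;
    lets the CSV reader report the unsplit line even for quoted multi-line
    records."""

    def __init__(self, it: Iterator[str]):
        self._it = it
        self.chunks: list[str] = []

    def __iter__(self) -> "_Recorder":
        return self

    def __next__(self) -> str:
        line = next(self._it)
        self.chunks.append(line)
        return line

    def take(self) -> str:
        text = "".join(self.chunks).strip("\r\n")
        self.chunks.clear()
        return text


def read_table(
    path: str | Path, dialect: Dialect | None = None, lossy: bool = False
) -> tuple[list[str], Iterator[RawRow]]:
    """Open *path* once and return ``(header, row_iterator)``.

    The iterator yields every non-comment, non-blank line after the header
    in constant memory.  Rows are split on the delimiter (RFC 4180 quoting
    for CSV); a field count differing from the header is *not* an error
    here — the parser engine decides the ragged-row policy.
    """
    if dialect is None:
        dialect = detect_dialect(path)
    fh = _open_text(path, dialect, lossy=lossy)
    header: list[str] | None = None
    try:
        for line in fh:
            if not line.strip():
                continue
            if _is_comment(line, dialect):
                continue
            header = _header_from_line(line, dialect)
            if header is not None:
                break
    except UnicodeDecodeError as exc:
        fh.close()
        raise DecodeError(f"{path}: undecodable bytes before header: {exc}") from None
    if header is None:
        fh.close()
        raise HeaderError(f"{path}: no header line found")

    def _rows() -> Iterator[RawRow]:
        n = 0
        try:
            with fh:
                if dialect.format_tag == "CSV":
                    rec = _Recorder(fh)
                    for values in csv.reader(rec):
                        raw = rec.take()
                        if not values or all(not v for v in values) and not raw.strip():
                            continue
                        n += 1
                        yield RawRow(values, n, raw)
                else:
                    for line in fh:
                        if not line.strip():
                            continue
                        if _is_comment(line, dialect):
                            continue
                        n += 1
                        text = line.rstrip("\r\n")
                        yield RawRow(text.split(dialect.delimiter), n, text)
        except UnicodeDecodeError as exc:
            raise DecodeError(
                f"{path}: undecodable bytes after data row {n}: {exc}"
            ) from None

    return header, _rows()


def read_header(path: str | Path, dialect: Dialect | None = None, lossy: bool = False) -> list[str]:
    """Return the ordered column names of *path* (trimmed, deduplicated;
    VCF's leading ``#`` stripped)."""
    header, rows = read_table(path, dialect, lossy=lossy)
    rows.close()  # type: ignore[attr-defined]
    return header


def iter_rows(
    path: str | Path, dialect: Dialect | None = None, lossy: bool = False
) -> Iterator[RawRow]:
    """Stream the data rows of *path* (see :func:`read_table`)."""
    _, rows = read_table(path, dialect, lossy=lossy)
    return rows
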