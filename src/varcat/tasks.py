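"""The four user-facing tasks: find files, cat, group-by, count.

``find_files`` walks a directory tree, pairs every variant file with the
nearest-ancestor annotation whose patterns match it, and emits the pairs
in lexicographic path order.  ``cat`` streams the unified records of all
pairs; ``group_by`` partitions them by a key field; ``count`` tallies
records matching an optional single-comparison where clause.

Group-by and count accept ``workers``: the unit of parallel work is one
input file and results are merged by lexicographic path order, so the
output is byte-identical for any worker count.
"""

from __future__ import annotations

import csv
import io
import logging
import multiprocessing
import os
import re
from dataclasses import dataclass
from enum import Enum
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Iterator, Sequence

from .engine import ParsedRecord, output_columns, parse_file
from .errors import (
    ColumnMismatchError,
    AmbiguousAnnotationError,
    SchemaValidationError,
    VarcatError,
    WhereEvaluationError,
    WhereParseError,
)
from .plugins import get_registry
from .readers import detect_dialect, read_header
from .schema import AnnotationSchema, load_annotation, normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "WhereClause", "WhereOp", "GroupResult", "CountResult",
    "find_files", "cat", "group_by", "count", "parse_where", "evaluate_where",
]

_VARIANT_EXTS = {".csv", ".tsv", ".txt", ".maf", ".vcf"}


# ---------------------------------------------------------------------------
# where clauses

class WhereOp(str, Enum):
    EQ = "=="
    NE = "!="
    LT = "<"
    LE = "<="
    GT = ">"
    GE = ">="


_ORDERED_OPS = (WhereOp.LT, WhereOp.LE, WhereOp.GT, WhereOp.GE)


@dataclass(frozen=True)
class WhereClause:
    """One comparison ``FIELD OP LITERAL`` filtering parsed records."""

    field: str
    op: WhereOp
    literal: str


_WHERE_RE = re.compile(
    r"""^\s*
        (?P<field>[^\s<>!=]+)\s*
        (?P<op>==|!=|<=|>=|<|>)\s*
        (?P<lit>.*?)\s*$""",
    re.VERBOSE,
)


def parse_where(text: str) -> WhereClause:
    """Parse ``FIELD OP LITERAL`` with OP in {==, !=, <, <=, >, >=}.

    Literals may be double-quoted to embed spaces; exactly one comparison
    per clause.
    """
    if not text or not text.strip():
        raise WhereParseError("empty where clause")
    m = _WHERE_RE.match(text)
    if m is None:
        raise WhereParseError(f"cannot parse condition {text!r}: expected FIELD OP LITERAL")
    field, op_text, literal = m.group("field"), m.group("op"), m.group("lit")
    if not literal:
        raise WhereParseError(f"missing literal after operator in {text!r}")
    if literal.startswith('"'):
        if len(literal) < 2 or not literal.endswith('"'):
            raise WhereParseError(f"unterminated quoted literal in {text!r}")
        literal = literal[1:-1]
    elif re.search(r"\s", literal):
        raise WhereParseError(
            f"unexpected token {literal.split()[1]!r} in {text!r}: "
            "quote the literal or use a single comparison"
        )
    return WhereClause(field=field, op=WhereOp(op_text), literal=literal)


def _as_number(text: str) -> float | None:
    try:
        return float(text)
    except (TypeError, ValueError):
        return None


def evaluate_where(
    clause: WhereClause,
    values: dict[str, str],
    lenient: bool = False,
    counters: dict[str, int] | None = None,
    provenance: str = "",
) -> bool:
    """Evaluate one clause against a record's values.

    Ordered operators (<, <=, >, >=) require both sides to parse as
    decimal numbers; a non-numeric side is a hard
    :class:`WhereEvaluationError` by default, or evaluates false with a
    counted warning under *lenient*.  ==/!= compare numerically when both
    sides are numeric and as strings otherwise.
    """
    left = values.get(clause.field, "")
    ln, rn = _as_number(left), _as_number(clause.literal)
    if clause.op in _ORDERED_OPS:
        if ln is None or rn is None:
            if lenient:
                if counters is not None:
                    counters["where_errors"] = counters.get("where_errors", 0) + 1
                return False
            bad = left if ln is None else clause.literal
            raise WhereEvaluationError(
                f"{provenance}numeric comparison '{clause.field} {clause.op.value} "
                f"{clause.literal}' against non-numeric value {bad!r}"
            )
        return {
            WhereOp.LT: ln < rn,
            WhereOp.LE: ln <= rn,
            WhereOp.GT: ln > rn,
            WhereOp.GE: ln >= rn,
        }[clause.op]
    if ln is not None and rn is not None:
        equal = ln == rn
    else:
        equal = left == clause.literal
    return equal if clause.op is WhereOp.EQ else not equal


# ---------------------------------------------------------------------------
# discovery

def _is_annotation_candidate(path: Path) -> bool:
    """Annotation files are YAML documents whose top level contains a
    ``pattern`` key; other YAML files (e.g. fixture manifests) are not
    annotations."""
    if path.suffix.lower() not in (".yaml", ".yml"):
        return False
    try:
        import yaml

        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except Exception:
        return False
    return isinstance(doc, dict) and "pattern" in doc


def find_files(
    root: str | Path,
    name_filter: str | None = None,
    annotation: str | Path | None = None,
) -> Iterator[tuple[Path, AnnotationSchema]]:
    """Pair every input file under *root* with its governing annotation.

    Without an override, annotations are discovered in the tree and the
    nearest-ancestor annotation whose patterns match a file governs it
    (an annotation with ``recursive: false`` only governs its own
    directory); two matching annotations in the same directory is an
    error.  With *annotation*, that single schema governs the whole tree.
    Pairs are emitted in lexicographic path order.
    """
    root = Path(root)
    if not root.is_dir():
        raise VarcatError(f"input directory not found: {root}")

    override = load_annotation(annotation) if annotation is not None else None

    all_files: list[Path] = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        for fname in sorted(filenames):
            all_files.append(Path(dirpath) / fname)

    ann_by_dir: dict[Path, list[AnnotationSchema]] = {}
    candidates: set[Path] = set()
    if override is None:
        for path in all_files:
            if _is_annotation_candidate(path):
                candidates.add(path)
                ann_by_dir.setdefault(path.parent, []).append(load_annotation(path))

    pairs: list[tuple[Path, AnnotationSchema]] = []
    for path in all_files:
        if path in candidates:
            continue
        name = path.name
        if override is not None:
            if override.matches(name):
                pairs.append((path, override))
            continue
        governing: AnnotationSchema | None = None
        directory = path.parent
        immediate = True
        while True:
            matching = [
                s for s in ann_by_dir.get(directory, ())
                if s.matches(name) and (s.recursive or immediate)
            ]
            if len(matching) > 1:
                raise AmbiguousAnnotationError(
                    f"{path}: {len(matching)} annotations in {directory} match"
                )
            if matching:
                governing = matching[0]
                break
            if directory == root:
                break
            directory = directory.parent
            immediate = False
        if governing is None:
            suffix = name[:-3] if name.endswith(".gz") else name
            if Path(suffix).suffix.lower() in _VARIANT_EXTS:
                logger.warning("%s: no applicable annotation; skipped", path)
            continue
        pairs.append((path, governing))

    for path, schema in sorted(pairs, key=lambda p: str(p[0])):
        if name_filter is not None:
            if any(ch in name_filter for ch in "*?["):
                if not fnmatchcase(path.name, name_filter):
                    continue
            elif name_filter not in path.name:
                continue
        yield path, schema


# ---------------------------------------------------------------------------
# parsing across pairs (sequential or parallel)

def _parse_pair_worker(job) -> tuple[list[ParsedRecord], dict[str, int]]:
    path, schema, skip_bad_rows, lossy, plugin_dir = job
    registry = get_registry(plugin_dir)
    stats: dict[str, int] = {}
    records = list(
        parse_file(path, schema, registry=registry, skip_bad_rows=skip_bad_rows,
                   lossy=lossy, stats=stats)
    )
    return records, stats


def _parse_all(
    pairs: Sequence[tuple[Path, AnnotationSchema]],
    workers: int = 1,
    skip_bad_rows: bool = False,
    lossy: bool = False,
    plugin_dir: str | None = None,
    stats: dict[str, int] | None = None,
) -> list[list[ParsedRecord]]:
    """Parse every (file, schema) pair, preserving pair order.

    The unit of work is one file; merging by the already-sorted pair order
    keeps results identical for any number of workers.
    """
    if workers < 1:
        raise VarcatError(f"workers must be >= 1, got {workers}")
    jobs = [(str(p), s, skip_bad_rows, lossy, plugin_dir) for p, s in pairs]
    if workers == 1 or len(jobs) <= 1:
        results = [_parse_pair_worker(job) for job in jobs]
    else:
        with multiprocessing.Pool(min(workers, len(jobs))) as pool:
            results = pool.map(_parse_pair_worker, jobs)
    out: list[list[ParsedRecord]] = []
    for records, st in results:
        out.append(records)
        if stats is not None:
            for k, v in st.items():
                stats[k] = stats.get(k, 0) + v
    return out


def _check_field_known(field: str, schema: AnnotationSchema, what: str) -> None:
    if schema.columns is None:
        return  # header mode: columns only known per file
    known = {normalize_name(c) for c in schema.columns}
    if normalize_name(field) not in known:
        raise SchemaValidationError(
            f"{what} field '{field}' is not a column of the schema "
            f"({', '.join(schema.columns)})"
        )


# ---------------------------------------------------------------------------
# the tasks

def _serialize_row(cells: Sequence[str], fmt: str) -> str:
    if fmt == "csv":
        buf = io.StringIO()
        csv.writer(buf, lineterminator="").writerow(list(cells))
        return buf.getvalue()
    return "\t".join(cells)


def cat(
    root: str | Path,
    annotation: str | Path | None = None,
    header: bool = True,
    *,
    name_filter: str | None = None,
    output_format: str | None = None,
    skip_bad_rows: bool = False,
    lossy: bool = False,
    plugin_dir: str | None = None,
    stats: dict[str, int] | None = None,
) -> Iterator[str]:
    """Stream the unified output lines for every pair under *root*.

    One header line (if *header*), then one line per kept record,
    serialized per the schema's output format (or *output_format*
    override); files in lexicographic order, rows in file order.  All
    files must resolve to the same output columns, else
    :class:`ColumnMismatchError`.
    """
    pairs = list(find_files(root, name_filter=name_filter, annotation=annotation))
    if not pairs:
        logger.warning("%s: no input files matched any annotation", root)
        return
    fmt = output_format or pairs[0][1].output_format
    registry = get_registry(plugin_dir)
    ref_cols: list[str] | None = None
    emitted_header = False
    for path, schema in pairs:
        cols = output_columns(schema, read_header(path, detect_dialect(path), lossy=lossy))
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise ColumnMismatchError(
                f"{path}: output columns {cols} differ from {ref_cols}; "
                "cat requires a single unified schema"
            )
        if header and not emitted_header:
            yield _serialize_row(ref_cols, fmt)
            emitted_header = True
        for record in parse_file(path, schema, registry=registry,
                                 skip_bad_rows=skip_bad_rows, lossy=lossy, stats=stats):
            yield _serialize_row(list(record.values.values()), fmt)


@dataclass
class GroupResult:
    """All kept records sharing one value of the group key."""

    key: str
    records: list[ParsedRecord]

    @property
    def size(self) -> int:
        return len(self.records)


@dataclass
class CountResult:
    total: int
    groups: dict[str, int] | None = None


def group_by(
    root: str | Path,
    key_field: str,
    where: WhereClause | str | None = None,
    workers: int = 1,
    *,
    annotation: str | Path | None = None,
    name_filter: str | None = None,
    lenient_where: bool = False,
    skip_bad_rows: bool = False,
    lossy: bool = False,
    plugin_dir: str | None = None,
    stats: dict[str, int] | None = None,
) -> list[GroupResult]:
    """Partition all kept (and where-surviving) records by *key_field*.

    Groups are sorted by key; within a group records follow (file
    lexicographic, row) order.  A record whose key is unresolvable falls
    into the group labelled with the sentinel — losing rows silently
    would violate conservation.  Output is identical for any workers >= 1.
    """
    clause = parse_where(where) if isinstance(where, str) else where
    pairs = list(find_files(root, name_filter=name_filter, annotation=annotation))
    if pairs:
        _check_field_known(key_field, pairs[0][1], "group-by")
        if clause is not None:
            _check_field_known(clause.field, pairs[0][1], "where")
    per_file = _parse_all(pairs, workers=workers, skip_bad_rows=skip_bad_rows,
                          lossy=lossy, plugin_dir=plugin_dir, stats=stats)
    groups: dict[str, list[ParsedRecord]] = {}
    counters = stats if stats is not None else {}
    for (path, schema), records in zip(pairs, per_file):
        sentinel = schema.missing_sentinel
        for record in records:
            if clause is not None and not evaluate_where(
                clause, record.values, lenient=lenient_where, counters=counters,
                provenance=f"{record.source}:{record.row_number}: ",
            ):
                continue
            key = record.values.get(key_field)
            if key is None:
                # case-insensitive fallback, then sentinel
                wanted = normalize_name(key_field)
                key = next(
                    (v for k, v in record.values.items() if normalize_name(k) == wanted),
                    sentinel,
                )
            groups.setdefault(key, []).append(record)
    return [GroupResult(key, records) for key, records in sorted(groups.items())]


def count(
    root: str | Path,
    where: WhereClause | str | None = None,
    group_key: str | None = None,
    workers: int = 1,
    *,
    annotation: str | Path | None = None,
    name_filter: str | None = None,
    lenient_where: bool = False,
    skip_bad_rows: bool = False,
    lossy: bool = False,
    plugin_dir: str | None = None,
    stats: dict[str, int] | None = None,
) -> CountResult:
    """Number of kept records satisfying *where*; per-group totals when
    *group_key* is given (they always sum to the total)."""
    clause = parse_where(where) if isinstance(where, str) else where
    if group_key is not None:
        grouped = group_by(
            root, group_key, where=clause, workers=workers, annotation=annotation,
            name_filter=name_filter, lenient_where=lenient_where,
            skip_bad_rows=skip_bad_rows, lossy=lossy, plugin_dir=plugin_dir, stats=stats,
        )
        per_group = {g.key: g.size for g in grouped}
        return CountResult(total=sum(per_group.values()), groups=per_group)
    pairs = list(find_files(root, name_filter=name_filter, annotation=annotation))
    if pairs and clause is not None:
        _check_field_known(clause.field, pairs[0][1], "where")
    per_file = _parse_all(pairs, workers=workers, skip_bad_rows=skip_bad_rows,
                          lossy=lossy, plugin_dir=plugin_dir, stats=stats)
    counters = stats if stats is not None else {}
    total = 0
    for records in per_file:
        for record in records:
            if clause is None or evaluate_where(
                clause, record.values, lenient=lenient_where, counters=counters,
                provenance=f"{record.source}:{record.row_number}: ",
            ):
                total += 1
    return CountResult(total=total)
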