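"""The core transformation: apply an annotation schema to raw rows.

For every data row of an input file the engine resolves each output column
in schema order — so a plugin or later column may depend on earlier ones —
and yields a :class:`ParsedRecord` whose key set and order are identical
across every file parsed under the same schema.  All values are strings;
an optional field that cannot be resolved yields the schema's
missing-value sentinel, while a required one aborts the file with
provenance (path and 1-based data-row number).

Ragged rows (field count != header count) are a hard error by default;
``skip_bad_rows=True`` demotes them to a counted, logged skip.  Silent
truncation corrupts cohort aggregation, so there is no middle ground.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Mapping

from .errors import FieldResolutionError, PluginError, RaggedRowError
from .readers import RawRow, detect_dialect, read_table
from .schema import AnnotationSchema, FieldDefinition, FieldKind, normalize_name

logger = logging.getLogger(__name__)

__all__ = ["ParsedRecord", "Context", "resolve_field", "apply_exclusions",
           "output_columns", "parse_file"]


@dataclass
class ParsedRecord:
    """One unified output row: ordered field-name -> string-value pairs."""

    values: dict[str, str]
    source: str
    row_number: int


@dataclass
class Context:
    """Per-row parsing state handed to plugins.

    Plugins may read ``record_in_progress`` (the columns resolved so far,
    in schema order) but must not reorder or rename it.
    """

    source_path: str
    file_name: str
    dir_name: str
    header: list[str]
    raw_row: RawRow
    record_in_progress: dict[str, str]
    schema_field: FieldDefinition | None = None
    sentinel: str = ""
    header_index: dict[str, int] | None = dc_field(default=None, repr=False)

    def header_value(self, name: str) -> str | None:
        """Cell of the current row under header *name* (case-insensitive,
        trimmed), or None if the column is absent."""
        if self.header_index is None:
            self.header_index = _index_header(tuple(self.header))
        idx = self.header_index.get(normalize_name(name))
        if idx is None or idx >= len(self.raw_row.values):
            return None
        return self.raw_row.values[idx]


@lru_cache(maxsize=None)
def _compiled(pattern: str) -> re.Pattern[str]:
    return re.compile(pattern)


def _index_header(header: tuple[str, ...]) -> dict[str, int]:
    index: dict[str, int] = {}
    for i, name in enumerate(header):
        index.setdefault(normalize_name(name), i)
    return index


def _missing(defn: FieldDefinition, ctx: Context, why: str) -> str:
    if defn.required:
        raise FieldResolutionError(
            f"{ctx.source_path}:{ctx.raw_row.row_number}: "
            f"required field '{defn.name}' unresolvable: {why}"
        )
    return ctx.sentinel


def resolve_field(
    defn: FieldDefinition,
    ctx: Context,
    registry: Mapping[str, object] | None = None,
) -> str:
    """Resolve one field definition against the current row context."""
    ctx.schema_field = defn
    kind = defn.kind
    if kind is FieldKind.STATIC:
        return defn.value if defn.value is not None else ctx.sentinel
    if kind is FieldKind.INTERNAL:
        for alias in defn.aliases or ():
            cell = ctx.header_value(alias)
            if cell is not None:
                return cell
        return _missing(defn, ctx, f"no alias of {list(defn.aliases or ())} in header")
    if kind in (FieldKind.FILENAME, FieldKind.DIRNAME):
        subject = ctx.file_name if kind is FieldKind.FILENAME else ctx.dir_name
        m = _compiled(defn.regex or "") .search(subject)
        if m is None:
            return _missing(defn, ctx, f"regex {defn.regex!r} has no match on '{subject}'")
        return m.group(1)
    if kind is FieldKind.MAPPING:
        key = None
        for alias in defn.aliases or ():
            key = ctx.header_value(alias)
            if key is not None:
                break
        if key is None:
            return _missing(defn, ctx, f"no alias of {list(defn.aliases or ())} in header")
        table = defn.mapping
        if table is None:
            from .schema import load_mapping_table

            table = load_mapping_table(defn.mapping_file or "", defn.key_column or "",
                                       defn.value_column or "")
            defn.mapping = table
        if key not in table:
            return _missing(defn, ctx, f"key '{key}' absent from {defn.mapping_file}")
        return table[key]
    if kind is FieldKind.PLUGIN:
        if registry is None:
            from .plugins import get_registry

            registry = get_registry(None)
        plugin = registry.get(defn.plugin_name or "")
        if plugin is None:
            raise PluginError(
                f"{ctx.source_path}:{ctx.raw_row.row_number}: "
                f"field '{defn.name}': no plugin named '{defn.plugin_name}'"
            )
        try:
            return str(plugin.process(ctx))  # type: ignore[attr-defined]
        except Exception as exc:
            raise PluginError(
                f"{ctx.source_path}:{ctx.raw_row.row_number}: "
                f"plugin '{defn.plugin_name}' failed: {exc}"
            ) from exc
    raise AssertionError(f"unhandled field kind {kind}")  # pragma: no cover


def output_columns(schema: AnnotationSchema, header: list[str]) -> list[str]:
    """The ordered output column names for one input file.

    With explicit ``columns`` the schema's list is used as written.  In
    header mode the input header (minus ``exclude_columns``) is used, with
    field-definition columns substituted in place or appended at the end.
    """
    if schema.columns is not None:
        return list(schema.columns)
    excluded = {normalize_name(e) for e in schema.excluded_columns}
    cols = [h for h in header if normalize_name(h) not in excluded]
    present = {normalize_name(c) for c in cols}
    for d in schema.field_defs:
        key = normalize_name(d.name)
        if key in present:
            cols = [d.name if normalize_name(c) == key else c for c in cols]
        else:
            cols.append(d.name)
    return cols


def apply_exclusions(record: ParsedRecord, schema: AnnotationSchema) -> bool:
    """Keep/drop decision: drop iff any (field, value) exclusion matches
    exactly (string equality).  Column exclusion has already happened at
    record construction."""
    for fname, value in schema.exclusions:
        if record.values.get(fname, None) == value:
            return False
        # exclusion field names follow the same case-insensitive match
        key = normalize_name(fname)
        for k, v in record.values.items():
            if normalize_name(k) == key and v == value:
                return False
    return True


def parse_file(
    path: str | Path,
    schema: AnnotationSchema,
    *,
    registry: Mapping[str, object] | None = None,
    skip_bad_rows: bool = False,
    lossy: bool = False,
    stats: dict[str, int] | None = None,
) -> Iterator[ParsedRecord]:
    """Stream unified records from one input file under one schema.

    Records appear in source-row order.  *stats*, when given, is updated in
    place with ``rows_read``, ``rows_kept``, ``rows_skipped`` (ragged rows
    under ``skip_bad_rows``) and ``rows_excluded`` (row-drop rules).
    """
    path = Path(path)
    dialect = detect_dialect(path)
    header, rows = read_table(path, dialect, lossy=lossy)
    cols = output_columns(schema, header)
    defs = {normalize_name(d.name): d for d in schema.field_defs}
    header_index = _index_header(tuple(header))
    file_name = path.name
    dir_name = path.resolve().parent.name
    if stats is None:
        stats = {}
    for key in ("rows_read", "rows_kept", "rows_skipped", "rows_excluded"):
        stats.setdefault(key, 0)

    for raw in rows:
        stats["rows_read"] += 1
        if len(raw.values) != len(header):
            if skip_bad_rows:
                stats["rows_skipped"] += 1
                logger.warning(
                    "%s:%d: skipped ragged row (%d fields, header has %d)",
                    path, raw.row_number, len(raw.values), len(header),
                )
                continue
            raise RaggedRowError(
                f"{path}:{raw.row_number}: row has {len(raw.values)} fields "
                f"but the header has {len(header)}"
            )
        values: dict[str, str] = {}
        ctx = Context(
            source_path=str(path),
            file_name=file_name,
            dir_name=dir_name,
            header=header,
            raw_row=raw,
            record_in_progress=values,
            sentinel=schema.missing_sentinel,
            header_index=header_index,
        )
        for col in cols:
            defn = defs.get(normalize_name(col))
            if defn is not None:
                values[col] = resolve_field(defn, ctx, registry)
            else:
                cell = ctx.header_value(col)
                values[col] = schema.missing_sentinel if cell is None else cell
        record = ParsedRecord(values, str(path), raw.row_number)
        if not apply_exclusions(record, schema):
            stats["rows_excluded"] += 1
            continue
        stats["rows_kept"] += 1
        yield record
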