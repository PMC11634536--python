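"""Annotation schemas: the declarative rule set that governs all parsing.

An annotation file is a YAML document placed next to (or above) the variant
files it describes.  It declares which files to read (``pattern``), which
output columns to produce (``columns``), and how each column's value is
obtained (``annotation``).  Columns without an explicit definition pass
through from the input header, matched case-insensitively after trimming —
MAF dialects famously disagree on header casing.

Top-level keys::

    pattern:          list of file-name globs (required, non-empty)
    recursive:        search the whole subtree (default true)
    format:           output format, "tsv" or "csv" (default tsv)
    columns:          ordered output field names; omit to derive from each
                      input header (header mode)
    exclude_columns:  input columns omitted from header-mode output
    exclude_rows:     list of {field, value} row-drop rules
    missing_value:    string emitted for unresolvable optional fields ("")
    annotation:       list of field definitions, keyed by ``type``

Field-definition types and their keys::

    static    value
    internal  aliases          (ordered input-header names to try)
    filename  regex            (one capture group, applied to the file name)
    dirname   regex            (one capture group, applied to the parent dir)
    mapping   aliases, file, key_column, value_column
    plugin    plugin           (registered plugin identifier)

Every definition also accepts ``field`` (the output name, required) and
``required`` (default false; unresolvable required fields abort the file,
optional ones yield the missing-value sentinel).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field as dc_field, replace
from enum import Enum
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Iterable

import yaml

from .errors import MappingTableError, SchemaSyntaxError, SchemaValidationError

__all__ = [
    "FieldKind",
    "FieldDefinition",
    "AnnotationSchema",
    "load_annotation",
    "serialize_annotation",
    "load_mapping_table",
    "normalize_name",
]


def normalize_name(name: str) -> str:
    """Normalize a field/header name for matching: trim then casefold."""
    return name.strip().casefold()


class FieldKind(str, Enum):
    STATIC = "static"
    INTERNAL = "internal"
    FILENAME = "filename"
    DIRNAME = "dirname"
    MAPPING = "mapping"
    PLUGIN = "plugin"


# keys each kind requires beyond {type, field, required}
_KIND_KEYS: dict[FieldKind, set[str]] = {
    FieldKind.STATIC: {"value"},
    FieldKind.INTERNAL: {"aliases"},
    FieldKind.FILENAME: {"regex"},
    FieldKind.DIRNAME: {"regex"},
    FieldKind.MAPPING: {"aliases", "file", "key_column", "value_column"},
    FieldKind.PLUGIN: {"plugin"},
}

_TOP_KEYS = {
    "pattern",
    "recursive",
    "format",
    "columns",
    "exclude_columns",
    "exclude_rows",
    "missing_value",
    "annotation",
}


@dataclass
class FieldDefinition:
    """One rule for producing one output column."""

    name: str
    kind: FieldKind
    value: str | None = None
    aliases: tuple[str, ...] | None = None
    regex: str | None = None
    mapping_file: str | None = None
    key_column: str | None = None
    value_column: str | None = None
    plugin_name: str | None = None
    required: bool = False
    # loaded lookup table; derived from mapping_file, so excluded from equality
    mapping: dict[str, str] | None = dc_field(default=None, compare=False, repr=False)


@dataclass
class AnnotationSchema:
    """The validated rule set parsed from one annotation file."""

    patterns: tuple[str, ...]
    columns: tuple[str, ...] | None = None
    field_defs: tuple[FieldDefinition, ...] = ()
    excluded_columns: tuple[str, ...] = ()
    exclusions: tuple[tuple[str, str], ...] = ()
    recursive: bool = True
    output_format: str = "tsv"
    missing_sentinel: str = ""
    source_path: str | None = dc_field(default=None, compare=False)

    def matches(self, file_name: str) -> bool:
        """True if *file_name* (a basename) matches any of the globs."""
        return any(fnmatchcase(file_name, pat) for pat in self.patterns)

    def field_def_for(self, name: str) -> FieldDefinition | None:
        key = normalize_name(name)
        for d in self.field_defs:
            if normalize_name(d.name) == key:
                return d
        return None


def _err(path: object, msg: str) -> SchemaValidationError:
    return SchemaValidationError(f"{path}: {msg}")


def _as_str_list(value: object, key: str, path: object) -> list[str]:
    if isinstance(value, str):
        return [value]
    if isinstance(value, list) and all(isinstance(v, str) for v in value):
        return list(value)
    raise _err(path, f"key '{key}' must be a string or list of strings")


def _parse_field_def(entry: object, path: object, ann_dir: Path) -> FieldDefinition:
    if not isinstance(entry, dict):
        raise _err(path, "entries of 'annotation' must be mappings")
    if "type" not in entry:
        raise _err(path, "annotation entry is missing 'type'")
    if "field" not in entry:
        raise _err(path, "annotation entry is missing 'field'")
    try:
        kind = FieldKind(str(entry["type"]).strip().lower())
    except ValueError:
        raise _err(path, f"unknown annotation type '{entry['type']}'") from None

    name = str(entry["field"])
    allowed = {"type", "field", "required"} | _KIND_KEYS[kind]
    extra = set(entry) - allowed
    if extra:
        raise _err(path, f"field '{name}': unexpected key(s) {sorted(extra)} for type '{kind.value}'")
    missing = _KIND_KEYS[kind] - set(entry)
    if missing:
        raise _err(path, f"field '{name}': missing key(s) {sorted(missing)} for type '{kind.value}'")

    required = bool(entry.get("required", False))
    defn = FieldDefinition(name=name, kind=kind, required=required)

    if kind is FieldKind.STATIC:
        defn.value = str(entry["value"])
    elif kind in (FieldKind.INTERNAL, FieldKind.MAPPING):
        aliases = _as_str_list(entry["aliases"], "aliases", path)
        if not aliases:
            raise _err(path, f"field '{name}': 'aliases' must be non-empty")
        defn.aliases = tuple(aliases)
    if kind in (FieldKind.FILENAME, FieldKind.DIRNAME):
        pattern = str(entry["regex"])
        try:
            compiled = re.compile(pattern)
        except re.error as exc:
            raise _err(path, f"field '{name}': invalid regex: {exc}") from None
        if compiled.groups != 1:
            raise _err(
                path,
                f"field '{name}': regex must contain exactly one capture group "
                f"(found {compiled.groups})",
            )
        defn.regex = pattern
    if kind is FieldKind.MAPPING:
        mapping_path = Path(str(entry["file"]))
        if not mapping_path.is_absolute():
            mapping_path = ann_dir / mapping_path
        defn.mapping_file = str(mapping_path)
        defn.key_column = str(entry["key_column"])
        defn.value_column = str(entry["value_column"])
        # fail fast: the table must resolve at load time
        defn.mapping = load_mapping_table(mapping_path, defn.key_column, defn.value_column)
    if kind is FieldKind.PLUGIN:
        defn.plugin_name = str(entry["plugin"])
    return defn


def load_annotation(path: str | Path) -> AnnotationSchema:
    """Load and validate one annotation file.

    Raises :class:`SchemaSyntaxError` for unparseable documents and
    :class:`SchemaValidationError` (naming the offending key and the file)
    for rule violations; a mapping table that does not resolve raises
    :class:`MappingTableError` immediately.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaSyntaxError(f"{path}: not valid YAML: {exc}") from None
    if not isinstance(doc, dict):
        raise SchemaSyntaxError(f"{path}: annotation document must be a mapping")

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise _err(path, f"unknown key(s) {sorted(unknown)}")
    if "pattern" not in doc:
        raise _err(path, "missing required key 'pattern'")

    patterns = tuple(_as_str_list(doc["pattern"], "pattern", path))
    if not patterns:
        raise _err(path, "'pattern' must be non-empty")

    recursive = doc.get("recursive", True)
    if not isinstance(recursive, bool):
        raise _err(path, "'recursive' must be a boolean")

    fmt = str(doc.get("format", "tsv")).strip().lower()
    if fmt not in ("tsv", "csv"):
        raise _err(path, f"'format' must be 'tsv' or 'csv', got '{fmt}'")

    sentinel = doc.get("missing_value", "")
    if not isinstance(sentinel, str):
        raise _err(path, "'missing_value' must be a string")

    columns: tuple[str, ...] | None = None
    if "columns" in doc and doc["columns"] is not None:
        cols = _as_str_list(doc["columns"], "columns", path)
        seen: set[str] = set()
        for c in cols:
            key = normalize_name(c)
            if key in seen:
                raise _err(path, f"duplicate column name '{c}'")
            seen.add(key)
        columns = tuple(cols)

    excluded = tuple(_as_str_list(doc.get("exclude_columns", []), "exclude_columns", path))
    if columns is not None:
        clash = {normalize_name(c) for c in columns} & {normalize_name(e) for e in excluded}
        if clash:
            raise _err(path, f"name(s) {sorted(clash)} appear in both columns and exclude_columns")

    defs: list[FieldDefinition] = []
    seen_defs: set[str] = set()
    for entry in doc.get("annotation", []) or []:
        defn = _parse_field_def(entry, path, path.parent)
        key = normalize_name(defn.name)
        if key in seen_defs:
            raise _err(path, f"field '{defn.name}' is defined more than once")
        seen_defs.add(key)
        if columns is not None and key not in {normalize_name(c) for c in columns}:
            raise _err(path, f"field '{defn.name}' is defined but not listed in columns")
        defs.append(defn)

    exclusions: list[tuple[str, str]] = []
    for rule in doc.get("exclude_rows", []) or []:
        if not isinstance(rule, dict) or set(rule) != {"field", "value"}:
            raise _err(path, "entries of 'exclude_rows' must be {field, value} mappings")
        fname = str(rule["field"])
        if columns is not None and normalize_name(fname) not in {
            normalize_name(c) for c in columns
        }:
            raise _err(path, f"exclude_rows names unknown field '{fname}'")
        exclusions.append((fname, str(rule["value"])))

    return AnnotationSchema(
        patterns=patterns,
        columns=columns,
        field_defs=tuple(defs),
        excluded_columns=excluded,
        exclusions=tuple(exclusions),
        recursive=recursive,
        output_format=fmt,
        missing_sentinel=sentinel,
        source_path=str(path),
    )


def serialize_annotation(schema: AnnotationSchema) -> str:
    """Emit annotation-file text that :func:`load_annotation` parses back
    to an equal schema (``source_path`` excepted)."""
    doc: dict[str, object] = {
        "pattern": list(schema.patterns),
        "recursive": schema.recursive,
        "format": schema.output_format,
        "missing_value": schema.missing_sentinel,
    }
    if schema.columns is not None:
        doc["columns"] = list(schema.columns)
    if schema.excluded_columns:
        doc["exclude_columns"] = list(schema.excluded_columns)
    if schema.exclusions:
        doc["exclude_rows"] = [{"field": f, "value": v} for f, v in schema.exclusions]
    if schema.field_defs:
        entries = []
        for d in schema.field_defs:
            entry: dict[str, object] = {"type": d.kind.value, "field": d.name}
            if d.kind is FieldKind.STATIC:
                entry["value"] = d.value
            if d.aliases is not None:
                entry["aliases"] = list(d.aliases)
            if d.regex is not None:
                entry["regex"] = d.regex
            if d.kind is FieldKind.MAPPING:
                entry["file"] = d.mapping_file
                entry["key_column"] = d.key_column
                entry["value_column"] = d.value_column
            if d.kind is FieldKind.PLUGIN:
                entry["plugin"] = d.plugin_name
            entry["required"] = d.required
            entries.append(entry)
        doc["annotation"] = entries
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def load_mapping_table(
    path: str | Path, key_column: str, value_column: str
) -> dict[str, str]:
    """Load a tab-delimited two-or-more-column lookup table with a header.

    Returns a dict from key string to value string.  Duplicate keys, a
    missing column, or an empty table raise :class:`MappingTableError`.
    """
    path = Path(path)
    if not path.exists():
        raise MappingTableError(f"mapping table not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MappingTableError(f"{path}: empty mapping table") from None
        norm_header = [normalize_name(h) for h in header]
        try:
            ki = norm_header.index(normalize_name(key_column))
        except ValueError:
            raise MappingTableError(f"{path}: no column named '{key_column}'") from None
        try:
            vi = norm_header.index(normalize_name(value_column))
        except ValueError:
            raise MappingTableError(f"{path}: no column named '{value_column}'") from None
        table: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) <= max(ki, vi):
                raise MappingTableError(f"{path}: line {lineno}: too few columns")
            key = row[ki]
            if key in table:
                raise MappingTableError(f"{path}: duplicate key '{key}'")
            table[key] = row[vi]
    if not table:
        raise MappingTableError(f"{path}: mapping table has no data rows")
    return table


def passthrough_schema(
    columns: Iterable[str],
    patterns: Iterable[str] = ("*.tsv", "*.csv"),
    output_format: str = "tsv",
) -> AnnotationSchema:
    """Convenience: a schema that passes the named columns straight through."""
    return AnnotationSchema(patterns=tuple(patterns), columns=tuple(columns),
                            output_format=output_format)


# re-exported for callers that tweak loaded schemas (tests, pipelines)
clone = replace
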