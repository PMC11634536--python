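"""Typed error hierarchy.

Every failure mode surfaces as a subclass of :class:`VarcatError` so callers
(and the CLI) can distinguish data/parse errors from programming errors.
Messages always carry provenance: the file path and, for per-row failures,
the 1-based data-row number.
"""


class VarcatError(Exception):
    """Base class for all errors raised by varcat."""


class SchemaSyntaxError(VarcatError):
    """The annotation document is not parseable YAML / not a mapping."""


class SchemaValidationError(VarcatError):
    """The annotation document parsed but violates a schema rule."""


class MappingTableError(VarcatError):
    """A mapping table is missing, empty, malformed, or has duplicate keys."""


class UnsupportedFormatError(VarcatError):
    """File extension does not correspond to a known dialect."""


class HeaderError(VarcatError):
    """No header line could be located in an input file."""


class DecodeError(VarcatError):
    """Undecodable bytes encountered while reading an input file."""


class RaggedRowError(VarcatError):
    """A data row's field count differs from the header's."""


class FieldResolutionError(VarcatError):
    """A required field could not be resolved for a row."""


class PluginError(VarcatError):
    """A plugin failed to load, scaffold, or execute."""


class WhereParseError(VarcatError):
    """A where-clause string does not match the FIELD OP LITERAL grammar."""


class WhereEvaluationError(VarcatError):
    """A numeric comparison was attempted on a non-numeric value (strict mode)."""


class ColumnMismatchError(VarcatError):
    """Files under one cat run resolve to different output column sets."""


class AmbiguousAnnotationError(VarcatError):
    """More than one annotation in the same directory matches a file."""


class FixtureError(VarcatError):
    """Fixture generation refused (e.g. non-empty output directory)."""
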