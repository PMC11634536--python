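"""Per-record transformation plugins.

A plugin is a class with a ``name`` and a ``process(context)`` method that
returns the string value for the plugin-defined output column.  The
context (see :class:`varcat.engine.Context`) exposes the file being
parsed, the current raw row, the header, and the record resolved so far;
``process`` must be deterministic given the context and may read — but not
reorder — earlier fields.

User plugins live in a directory with one subdirectory per plugin::

    my_plugins/
      my_filter/
        plugin.yaml   # descriptor: name, version, field, description
        plugin.py     # defines a top-level class ``Plugin``

``scaffold_plugin`` generates that layout ready to edit;
``get_registry`` merges user plugins over the built-ins (user wins on a
name collision, with a logged warning).
"""

from __future__ import annotations

import importlib.util
import logging
import re
import sys
from functools import lru_cache
from pathlib import Path

import yaml

from ..errors import PluginError
from .alteration import classify_alteration

logger = logging.getLogger(__name__)

__all__ = [
    "classify_alteration",
    "AlterationTypePlugin",
    "get_registry",
    "register_and_discover",
    "scaffold_plugin",
]


class AlterationTypePlugin:
    """Built-in: classify each row's REF/ALT pair as SNV/MNV/INS/DEL.

    Looks for the alleles first among already-resolved record fields, then
    directly in the input header, under the usual VCF and MAF spellings.
    """

    name = "alteration_type"

    REF_NAMES = ("REF", "Reference_Allele", "ref_allele")
    ALT_NAMES = ("ALT", "Tumor_Seq_Allele2", "alt_allele", "Tumor_Allele")

    @staticmethod
    def _find(context, names) -> str | None:
        wanted = {n.strip().casefold() for n in names}
        for key, value in context.record_in_progress.items():
            if key.strip().casefold() in wanted:
                return value
        for name in names:
            cell = context.header_value(name)
            if cell is not None:
                return cell
        return None

    def process(self, context) -> str:
        ref = self._find(context, self.REF_NAMES)
        alt = self._find(context, self.ALT_NAMES)
        if ref is None or alt is None:
            return "UNKNOWN"
        return classify_alteration(ref, alt)


def _builtin_registry() -> dict[str, object]:
    return {AlterationTypePlugin.name: AlterationTypePlugin()}


def _load_user_plugin(entry: Path) -> tuple[str, object]:
    descriptor = entry / "plugin.yaml"
    impl = entry / "plugin.py"
    if not impl.exists():
        raise PluginError(f"{entry}: user plugin has no plugin.py")
    name = entry.name
    if descriptor.exists():
        try:
            meta = yaml.safe_load(descriptor.read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise PluginError(f"{descriptor}: malformed descriptor: {exc}") from None
        if isinstance(meta, dict) and meta.get("name"):
            name = str(meta["name"])
    module_name = f"varcat_user_plugin_{entry.name}"
    spec = importlib.util.spec_from_file_location(module_name, impl)
    if spec is None or spec.loader is None:  # pragma: no cover
        raise PluginError(f"{impl}: cannot load plugin module")
    module = importlib.util.module_from_spec(spec)
    sys.modules[module_name] = module
    try:
        spec.loader.exec_module(module)
    except Exception as exc:
        raise PluginError(f"{impl}: error importing plugin: {exc}") from exc
    cls = getattr(module, "Plugin", None)
    if cls is None:
        raise PluginError(f"{impl}: plugin module defines no class 'Plugin'")
    instance = cls()
    if not callable(getattr(instance, "process", None)):
        raise PluginError(f"{impl}: Plugin has no callable 'process' method")
    return name, instance


def register_and_discover(user_plugin_dir: str | Path | None = None) -> dict[str, object]:
    """Built-ins plus user plugins from *user_plugin_dir* (if given).

    A user plugin whose name collides with a built-in wins, with a logged
    warning; a malformed user plugin raises :class:`PluginError` naming
    the entry.
    """
    registry = _builtin_registry()
    if user_plugin_dir is None:
        return registry
    root = Path(user_plugin_dir)
    if not root.is_dir():
        raise PluginError(f"plugin directory not found: {root}")
    for entry in sorted(p for p in root.iterdir() if p.is_dir()):
        if not (entry / "plugin.py").exists():
            continue
        name, plugin = _load_user_plugin(entry)
        if name in registry:
            logger.warning("user plugin '%s' (%s) overrides the built-in", name, entry)
        registry[name] = plugin
    return registry


@lru_cache(maxsize=None)
def _cached_registry(dir_key: str | None) -> dict[str, object]:
    return register_and_discover(dir_key)


def get_registry(user_plugin_dir: str | Path | None = None) -> dict[str, object]:
    """Cached registry lookup keyed by the plugin directory path (workers
    in a process pool rebuild it locally from this path)."""
    key = str(user_plugin_dir) if user_plugin_dir is not None else None
    return _cached_registry(key)


_IDENT = re.compile(r"^[A-Za-z_]\w*$")

_STUB_DESCRIPTOR = """\
name: {name}
version: 0.1.0
field: value produced by the '{name}' plugin
description: >
  Template plugin. Edit plugin.py to implement the transformation; the
  stub returns the schema's missing-value sentinel for every row.
"""

_STUB_IMPL = '''\
"""Template plugin '{name}'.

``process`` receives the per-row parsing context:

* ``context.source_path`` / ``context.file_name`` / ``context.dir_name``
* ``context.header``                 -- input column names
* ``context.raw_row.values``         -- the split input line
* ``context.record_in_progress``     -- output fields resolved so far
* ``context.header_value(name)``     -- case-insensitive cell lookup
* ``context.sentinel``               -- the schema's missing-value string

Return the string value for this plugin's output column.
"""


class Plugin:
    name = "{name}"

    def process(self, context):
        return context.sentinel
'''


def scaffold_plugin(
    name: str, target_dir: str | Path, force: bool = False
) -> list[Path]:
    """Create a ready-to-edit plugin template; returns the created paths.

    Refuses to overwrite an existing plugin of the same name unless
    *force* is true.
    """
    if not _IDENT.match(name):
        raise PluginError(f"'{name}' is not a valid plugin identifier")
    root = Path(target_dir) / name
    if root.exists() and any(root.iterdir()) and not force:
        raise PluginError(f"plugin '{name}' already exists at {root} (use force to overwrite)")
    root.mkdir(parents=True, exist_ok=True)
    descriptor = root / "plugin.yaml"
    impl = root / "plugin.py"
    descriptor.write_text(_STUB_DESCRIPTOR.format(name=name), encoding="utf-8")
    impl.write_text(_STUB_IMPL.format(name=name), encoding="utf-8")
    # a freshly scaffolded plugin must be discoverable without edits
    _cached_registry.cache_clear()
    return [descriptor, impl]
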