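from __future__ import annotations

import textwrap
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def write_file(tmp_path: Path):
    """Write dedented text under tmp_path and return the path."""

    def _write(relpath: str, text: str) -> Path:
        path = tmp_path / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(textwrap.dedent(text), encoding="utf-8")
        return path

    return _write


@pytest.fixture
def minimal_annotation(write_file):
    """A valid annotation: four pass-through columns plus one static field."""
    return write_file(
        "ann.yaml",
        """\
        pattern: ["*.maf"]
        columns: [CHROM, POS, REF, ALT, DATASET]
        annotation:
          - type: static
            field: DATASET
            value: cohortA
        """,
    )


@pytest.fixture
def cohort_tree(tmp_path: Path):
    """A small generated 2-cohort, 2-format tree with its manifest."""
    from varcat.fixtures import generate_cohorts

    root = tmp_path / "cohorts"
    manifest = generate_cohorts(root, n_cohorts=2, rows_per_file=50,
                                formats=("tsv", "vcf"), seed=7)
    return root, manifest
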