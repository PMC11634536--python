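"""Discovery, cat, group-by, count, where clauses, and parallelism."""

from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from varcat.errors import (
    AmbiguousAnnotationError,
    ColumnMismatchError,
    SchemaValidationError,
    WhereEvaluationError,
    WhereParseError,
)
from varcat.schema import load_annotation
from varcat.tasks import (
    WhereClause,
    WhereOp,
    cat,
    count,
    evaluate_where,
    find_files,
    group_by,
    parse_where,
)

from _naive import naive_filter_count, naive_group, naive_parse_file

ANN = """\
pattern: ["*.maf"]
columns: [CHROM, POS, DATASET]
annotation:
  - {type: dirname, field: DATASET, regex: '(.*)'}
"""


def _maf(n, start=1):
    lines = ["CHROM\tPOS"]
    lines += [f"{i}\t{i * 10}" for i in range(start, start + n)]
    return "\n".join(lines) + "\n"


class TestFindFiles:
    def test_pattern_filter(self, write_file, tmp_path):
        write_file("ann.yaml", ANN)
        write_file("a.maf", _maf(2))
        write_file("b.vcf", "##x\n#CHROM\tPOS\n1\t2\n")
        pairs = list(find_files(tmp_path))
        assert [p.name for p, _ in pairs] == ["a.maf"]
        assert pairs[0][1].patterns == ("*.maf",)

    def test_nearest_ancestor_wins(self, write_file, tmp_path):
        write_file("ann.yaml", ANN)
        write_file("sub/ann.yaml", ANN.replace("DATASET", "OTHER"))
        write_file("a.maf", _maf(1))
        write_file("sub/b.maf", _maf(1))
        pairs = {str(p.relative_to(tmp_path)): s for p, s in find_files(tmp_path)}
        assert "OTHER" in pairs["sub/b.maf"].columns
        assert "DATASET" in pairs["a.maf"].columns

    def test_non_recursive_annotation_governs_own_dir_only(self, write_file, tmp_path):
        write_file("ann.yaml", "recursive: false\n" + ANN)
        write_file("a.maf", _maf(1))
        write_file("sub/b.maf", _maf(1))
        assert [p.name for p, _ in find_files(tmp_path)] == ["a.maf"]

    def test_two_matching_annotations_in_one_dir_is_an_error(self, write_file, tmp_path):
        write_file("ann1.yaml", ANN)
        write_file("ann2.yaml", ANN)
        write_file("a.maf", _maf(1))
        with pytest.raises(AmbiguousAnnotationError):
            list(find_files(tmp_path))

    def test_manifest_yaml_is_not_an_annotation(self, write_file, tmp_path):
        write_file("manifest.yaml", "seed: 42\nfiles: []\n")
        write_file("ann.yaml", ANN)
        write_file("a.maf", _maf(1))
        assert [p.name for p, _ in find_files(tmp_path)] == ["a.maf"]

    def test_fixture_tree_matches_manifest(self, cohort_tree):
        root, manifest = cohort_tree
        pairs = list(find_files(root))
        assert sorted(str(p.relative_to(root)) for p, _ in pairs) == sorted(
            e["path"] for e in manifest.files
        )

    def test_name_filter(self, cohort_tree):
        root, _ = cohort_tree
        only_vcf = [p.name for p, _ in find_files(root, name_filter="*.vcf*")]
        assert only_vcf and all(".vcf" in n for n in only_vcf)


class TestParseWhere:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ('REF == "A"', WhereClause("REF", WhereOp.EQ, "A")),
            ("POS >= 1000", WhereClause("POS", WhereOp.GE, "1000")),
            ("X!=y", WhereClause("X", WhereOp.NE, "y")),
            ('NAME == "two words"', WhereClause("NAME", WhereOp.EQ, "two words")),
            ("POS<5", WhereClause("POS", WhereOp.LT, "5")),
        ],
    )
    def test_grammar(self, text, expected):
        assert parse_where(text) == expected

    @pytest.mark.parametrize("text", ["", "POS", "POS >=", "A == b == c",
                                      'X == "unterminated'])
    def test_malformed(self, text):
        with pytest.raises(WhereParseError):
            parse_where(text)

    def test_numeric_op_on_non_numeric_is_strict_error(self):
        clause = parse_where("POS >= abc")
        with pytest.raises(WhereEvaluationError):
            evaluate_where(clause, {"POS": "5"})
        counters: dict[str, int] = {}
        assert evaluate_where(clause, {"POS": "5"}, lenient=True,
                              counters=counters) is False
        assert counters["where_errors"] == 1

    def test_eq_numeric_vs_string_semantics(self):
        assert evaluate_where(parse_where("POS == 5.0"), {"POS": "5"}) is True
        assert evaluate_where(parse_where("REF == A"), {"REF": "A"}) is True
        assert evaluate_where(parse_where("REF != A"), {"REF": "C"}) is True


def _all_fixture_records(root, manifest):
    records = []
    for entry in sorted(manifest.files, key=lambda e: e["path"]):
        schema = load_annotation(root / entry["cohort"] / "annotation.yaml")
        records += naive_parse_file(root / entry["path"], schema)
    return records


class TestTasksOnFixture:
    def test_conservation_law(self, cohort_tree):
        """Sigma group sizes == count == cat data lines."""
        root, manifest = cohort_tree
        total = count(root).total
        lines = list(cat(root, header=True))
        assert total == manifest.total_rows == len(lines) - 1
        for key in ("DATASET", "ALT_TYPE", "SOURCE_FORMAT"):
            groups = group_by(root, key)
            assert sum(g.size for g in groups) == total

    def test_group_sizes_match_manifest_and_naive(self, cohort_tree):
        root, manifest = cohort_tree
        by_type = {g.key: g.size for g in group_by(root, "ALT_TYPE")}
        assert by_type == {k: v for k, v in manifest.types.items() if v}
        naive = naive_group(_all_fixture_records(root, manifest), "ALT_TYPE")
        assert by_type == naive
        by_ds = {g.key: g.size for g in group_by(root, "DATASET")}
        assert by_ds == {c: e["rows"] for c, e in manifest.cohorts.items()}

    def test_where_counts_match_brute_force(self, cohort_tree):
        root, manifest = cohort_tree
        records = _all_fixture_records(root, manifest)
        for text in ('FILTER == "LowQual"', "POS >= 50000000", 'ALT_TYPE != "SNV"',
                     "POS < 1"):
            field, op, lit = parse_where(text).field, parse_where(text).op.value, \
                parse_where(text).literal
            assert count(root, where=text).total == \
                naive_filter_count(records, field, op, lit)

    def test_filter_monotonicity(self, cohort_tree):
        root, _ = cohort_tree
        base = count(root).total
        assert count(root, where="POS >= 0").total <= base
        assert count(root, where='FILTER == "PASS"').total <= base

    def test_per_group_totals_sum_to_total(self, cohort_tree):
        root, _ = cohort_tree
        result = count(root, where='FILTER == "PASS"', group_key="DATASET")
        assert sum(result.groups.values()) == result.total

    def test_workers_do_not_change_results(self, cohort_tree):
        root, _ = cohort_tree
        ref_groups = None
        ref_count = None
        for workers in (1, 2, 4):
            groups = [(g.key, [tuple(r.values.items()) for r in g.records])
                      for g in group_by(root, "ALT_TYPE", workers=workers)]
            total = count(root, workers=workers).total
            if ref_groups is None:
                ref_groups, ref_count = groups, total
            assert groups == ref_groups
            assert total == ref_count

    def test_unknown_key_field_fails_before_parsing(self, cohort_tree):
        root, _ = cohort_tree
        with pytest.raises(SchemaValidationError, match="NO_SUCH"):
            group_by(root, "NO_SUCH")
        with pytest.raises(SchemaValidationError, match="NO_SUCH"):
            count(root, where='NO_SUCH == "x"')

    def test_unresolvable_group_key_falls_into_sentinel_group(
        self, write_file, tmp_path
    ):
        write_file(
            "c/ann.yaml",
            """\
            pattern: ["*.tsv"]
            columns: [CHROM, MAYBE]
            """,
        )
        write_file("c/x.tsv", "CHROM\n1\n2\n")
        groups = group_by(tmp_path / "c", "MAYBE")
        assert [(g.key, g.size) for g in groups] == [("", 2)]


class TestCat:
    def test_single_file_line_count(self, write_file, tmp_path):
        write_file("ann.yaml", ANN)
        write_file("a.maf", _maf(3))
        assert len(list(cat(tmp_path, header=True))) == 4
        assert len(list(cat(tmp_path, header=False))) == 3

    def test_cat_equals_count(self, cohort_tree):
        root, _ = cohort_tree
        assert len(list(cat(root, header=False))) == count(root).total

    def test_column_mismatch_across_schemas(self, write_file, tmp_path):
        write_file("a/ann.yaml", ANN)
        write_file("a/x.maf", _maf(1))
        write_file("b/ann.yaml", ANN.replace("[CHROM, POS, DATASET]",
                                             "[CHROM, DATASET]"))
        write_file("b/x.maf", _maf(1))
        with pytest.raises(ColumnMismatchError):
            list(cat(tmp_path))

    def test_empty_run_yields_no_lines(self, tmp_path):
        (tmp_path / "empty").mkdir()
        assert list(cat(tmp_path / "empty")) == []

    def test_csv_output_format(self, write_file, tmp_path):
        write_file("ann.yaml", ANN.replace("columns:", "format: csv\ncolumns:"))
        write_file("a.maf", _maf(1))
        lines = list(cat(tmp_path, header=True))
        assert lines[0] == "CHROM,POS,DATASET"

    def test_roundtrip_through_passthrough_schema(self, cohort_tree, tmp_path, write_file):
        """cat -> write TSV -> reparse via a pass-through schema reproduces
        the identical record multiset."""
        root, _ = cohort_tree
        lines = list(cat(root, header=True))
        out = tmp_path / "round"
        out.mkdir()
        (out / "unified.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        cols = lines[0].split("\t")
        write_file(
            "round/ann.yaml",
            "pattern: ['*.tsv']\ncolumns: [%s]\n" % ", ".join(cols),
        )
        again = list(cat(out, header=True))
        assert sorted(again) == sorted(lines)
        assert again[0] == lines[0]


@given(
    pos=st.lists(st.integers(0, 10**6), min_size=1, max_size=200),
    threshold=st.integers(0, 10**6),
)
def test_count_threshold_equals_brute_force(tmp_path_factory, pos, threshold):
    """where POS >= t on random records equals a brute-force filter count."""
    root = tmp_path_factory.mktemp("thr")
    (root / "ann.yaml").write_text(
        "pattern: ['*.tsv']\ncolumns: [POS]\n", encoding="utf-8"
    )
    (root / "x.tsv").write_text(
        "POS\n" + "".join(f"{p}\n" for p in pos), encoding="utf-8"
    )
    got = count(root, where=f"POS >= {threshold}").total
    assert got == sum(p >= threshold for p in pos)
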