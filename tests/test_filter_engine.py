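"""Rule parsing and evaluation: grammar, semantics, set algebra."""

import itertools
import random

import pytest

from helpers_oracle import (FD_TEXT, oracle_matching_keys, random_expr,
                            random_table, render_expr, serialize_rows)
from varsieve.errors import RuleError
from varsieve.filter_engine import (And, Comparison, Or, SetRule,
                                    apply_rules, build_primary_key,
                                    eval_comparison, eval_expr, parse_fr,
                                    set_op)
from varsieve.schema import FieldDef, FieldSchema, parse_fd
from varsieve.table_io import VariantRow, VariantTable, read_table

FR_TEXT = (
    "BuildingPrimarykey: Chr Start End Ref Alt\n"
    "FilteringRule:\n"
    "(Chr %e 1) | (Chr %e 3) : chr\n"
    "(Func.refGene %e exonic) * (ExAC_ALL %lt 0.005) : base\n"
    "# chr %int base : set_intersection\n"
)


class TestParseFr:
    def test_worked_three_rule_file(self):
        rs = parse_fr(FR_TEXT)
        assert rs.key_spec.fields == ("Chr", "Start", "End", "Ref", "Alt")
        assert rs.names == ["chr", "base", "set_intersection"]
        chr_rule = dict(rs.rules)["chr"]
        assert chr_rule == Or((Comparison("Chr", "%e", "1"),
                               Comparison("Chr", "%e", "3")))
        base = dict(rs.rules)["base"]
        assert base == And((Comparison("Func.refGene", "%e", "exonic"),
                            Comparison("ExAC_ALL", "%lt", "0.005")))
        setr = dict(rs.rules)["set_intersection"]
        assert setr == SetRule("chr", "%int", "base")

    @pytest.mark.parametrize(
        "text, match",
        [
            ("BuildingPrimarykey: K\nFilteringRule:\n"
             "# base %int chr2 : x\n", "unknown rule"),
            ("BuildingPrimarykey: K\nFilteringRule:\n"
             "((Chr %e 1) : y\n", "line 3.*missing '\\)'"),
            ("BuildingPrimarykey: K\nFilteringRule:\n"
             "Chr %e 1) : y\n", "extra '\\)'"),
            ("BuildingPrimarykey: K\nFilteringRule:\n"
             "Chr %zz 1 : y\n", "unknown operator"),
            ("BuildingPrimarykey: K\nFilteringRule:\n"
             "Chr %e 1 : a\nChr %e 2 : a\n", "duplicate rule name"),
            ("BuildingPrimarykey: K\nFilteringRule:\n"
             "Chr %e 1 : a\n# a %xor a : b\n", "unknown set operator"),
            ("FilteringRule:\nChr %e 1 : a\n", "BuildingPrimarykey"),
            ("BuildingPrimarykey: K\nFilteringRule:\nChr %e 1\n",
             "': <name>'"),
        ],
    )
    def test_malformed_fr_rejected_with_line(self, text, match):
        with pytest.raises(RuleError, match=match):
            parse_fr(text)

    def test_set_rule_only_references_earlier_rules(self):
        text = ("BuildingPrimarykey: K\nFilteringRule:\n"
                "# a %int b : c\nChr %e 1 : a\nChr %e 2 : b\n")
        with pytest.raises(RuleError, match="unknown rule 'a'"):
            parse_fr(text)

    def test_quoted_literal_permits_spaces_and_colon(self):
        rs = parse_fr('BuildingPrimarykey: K\nFilteringRule:\n'
                      'Pheno %m "breast cancer: type 1" : q\n')
        assert dict(rs.rules)["q"].literal == "breast cancer: type 1"


SCHEMA = parse_fd(
    "Name\tType\tdelimiter(req)\n"
    "Chr\tS\t\nStart\tI\t\nExAC_ALL\tD\t\nFunc.refGene\tS\t;\n"
)


def _row(**cells):
    base = {"Chr": None, "Start": None, "ExAC_ALL": None,
            "Func.refGene": None}
    base.update(cells)
    return VariantRow(base, 0, "t")


class TestEvalComparison:
    @pytest.mark.parametrize(
        "field, op, lit, cells, expected",
        [
            ("Chr", "%e", "1", {"Chr": "1"}, True),
            ("Chr", "%e", "1", {"Chr": "2"}, False),
            ("ExAC_ALL", "%lt", "0.005", {"ExAC_ALL": 0.01}, False),
            ("ExAC_ALL", "%lt", "0.005", {"ExAC_ALL": 0.001}, True),
            ("ExAC_ALL", "%lt", "0.005", {}, False),
            ("Func.refGene", "%m", "exon", {"Func.refGene": ["exonic"]}, True),
            ("Func.refGene", "%nm", "exon", {"Func.refGene": ["intronic"]},
             True),
            # missing fails even the negated operators
            ("Func.refGene", "%nm", "exon", {}, False),
            ("Chr", "%ne", "1", {}, False),
            ("Chr", "%ne", "1", {"Chr": "2"}, True),
            ("Start", "%ge", "100", {"Start": 100}, True),
            ("Start", "%gt", "100", {"Start": 100}, False),
            ("Start", "%le", "100", {"Start": 99}, True),
        ],
    )
    def test_comparison_semantics(self, field, op, lit, cells, expected):
        cmp = Comparison(field, op, lit)
        assert eval_comparison(cmp, _row(**cells), SCHEMA) is expected

    def test_multivalued_is_existential(self):
        """Brute force over all 1- and 2-element value combinations."""
        pool = ["exonic", "splicing", "intronic"]
        cmp = Comparison("Func.refGene", "%e", "exonic")
        for n in (1, 2):
            for combo in itertools.permutations(pool, n):
                row = _row(**{"Func.refGene": list(combo)})
                assert eval_comparison(cmp, row, SCHEMA) is \
                    ("exonic" in combo)

    def test_numeric_literal_validated_at_bind(self):
        from varsieve.filter_engine import bind_ruleset
        rs = parse_fr("BuildingPrimarykey: Chr\nFilteringRule:\n"
                      "ExAC_ALL %lt abc : r\n")
        with pytest.raises(RuleError, match="abc"):
            bind_ruleset(rs, SCHEMA)

    def test_order_op_on_string_field_rejected_at_bind(self):
        from varsieve.filter_engine import bind_ruleset
        rs = parse_fr("BuildingPrimarykey: Chr\nFilteringRule:\n"
                      "Chr %lt 5 : r\n")
        with pytest.raises(RuleError, match="numeric"):
            bind_ruleset(rs, SCHEMA)


class TestEvalExpr:
    def test_or_of_comparisons(self):
        expr = parse_fr(FR_TEXT).rules[0][1]
        assert eval_expr(expr, _row(Chr="3"), SCHEMA)
        assert not eval_expr(expr, _row(Chr="2"), SCHEMA)

    @pytest.mark.parametrize(
        "func, exac, expected",
        [(["exonic"], 0.004, True), (["exonic"], 0.2, False),
         (["intronic"], 0.004, False), (["exonic"], None, False)],
    )
    def test_and_of_comparisons(self, func, exac, expected):
        expr = parse_fr(FR_TEXT).rules[1][1]
        row = _row(**{"Func.refGene": func, "ExAC_ALL": exac})
        assert eval_expr(expr, row, SCHEMA) is expected

    def test_and_binds_tighter_than_or(self):
        """'A | B * C' must equal 'A | (B * C)' on all 8 assignments."""
        rs = parse_fr(
            "BuildingPrimarykey: Chr\nFilteringRule:\n"
            "Chr %e 1 | Func.refGene %e exonic * ExAC_ALL %lt 0.005 : r\n"
        )
        expr = rs.rules[0][1]
        for a, b, c in itertools.product([False, True], repeat=3):
            row = _row(
                Chr="1" if a else "9",
                **{"Func.refGene": ["exonic" if b else "intronic"],
                   "ExAC_ALL": 0.001 if c else 0.1},
            )
            assert eval_expr(expr, row, SCHEMA) is (a or (b and c))


class TestPrimaryKey:
    def test_join_rule(self):
        schema = FieldSchema((FieldDef("Chr", "S"), FieldDef("Start", "I"),
                              FieldDef("End", "I"), FieldDef("Ref", "S"),
                              FieldDef("Alt", "S")))
        row = VariantRow({"Chr": "1", "Start": 100, "End": 100,
                          "Ref": "A", "Alt": "G"}, 0, "t")
        spec = parse_fr(FR_TEXT).key_spec
        assert build_primary_key(row, spec, schema) == "1:100:100:A:G"

    def test_missing_serialized_as_dot(self):
        schema = FieldSchema((FieldDef("Chr", "S"), FieldDef("Start", "I")))
        row = VariantRow({"Chr": "1", "Start": None}, 0, "t")
        from varsieve.filter_engine import PrimaryKeySpec
        assert build_primary_key(
            row, PrimaryKeySpec(("Chr", "Start")), schema) == "1:."

    def test_duplicate_keys_first_occurrence_wins(self):
        schema = FieldSchema((FieldDef("Chr", "S"), FieldDef("Start", "I")))
        rows = [VariantRow({"Chr": "1", "Start": 5}, i, "t")
                for i in range(2)]
        table = VariantTable(schema, rows, "t")
        rs = parse_fr("BuildingPrimarykey: Chr Start\nFilteringRule:\n"
                      "Start %ge 0 : all\n")
        res = apply_rules([table], rs)
        assert res.keys("all") == ["1:5"]
        assert res.duplicate_keys["t"] == 1


class TestSetOp:
    def test_definitions(self):
        a = {"k1": 1, "k2": 2}
        b = {"k2": 9, "k3": 3}
        assert list(set_op(a, b, "%int")) == ["k2"]
        assert list(set_op(a, b, "%dif")) == ["k1"]
        assert list(set_op(a, b, "%uni")) == ["k1", "k2", "k3"]
        # rows come from the left operand on overlap
        assert set_op(a, b, "%uni")["k2"] == 2

    def test_algebra_on_random_key_sets(self):
        rng = random.Random(42)
        universe = [f"k{i}" for i in range(40)]
        for _ in range(100):
            a = {k: k for k in rng.sample(universe, rng.randint(0, 30))}
            b = {k: k for k in rng.sample(universe, rng.randint(0, 30))}
            i = set_op(a, b, "%int")
            u = set_op(a, b, "%uni")
            d = set_op(a, b, "%dif")
            assert len(i) + len(u) == len(a) + len(b)
            assert not set(i) & set(d)
            assert set(i) == set(a) & set(b)
            assert set(u) == set(a) | set(b)
            assert set(d) == set(a) - set(b)
            assert list(set_op(a, a, "%int")) == list(a)


class TestApplyRules:
    def test_ledger_counts_on_generated_fixture(self, bundle,
                                                bundle_schema):
        paths, ledger, _ = bundle
        table = read_table(paths["table"], bundle_schema)
        res = apply_rules([table], parse_fr(FR_TEXT))
        assert res.keys("chr") == ledger.keys_chr_in({"1", "3"})
        assert res.keys("base") == ledger.keys_exonic_and_exac_lt(0.005)
        base = set(ledger.keys_exonic_and_exac_lt(0.005))
        assert res.keys("set_intersection") == [
            k for k in ledger.keys_chr_in({"1", "3"}) if k in base
        ]

    def test_tautology_returns_all_rows(self, bundle, bundle_schema):
        paths, ledger, _ = bundle
        table = read_table(paths["table"], bundle_schema)
        rs = parse_fr("BuildingPrimarykey: Chr Start End Ref Alt\n"
                      "FilteringRule:\nStart %ge 0 : all\n")
        res = apply_rules([table], rs)
        assert res.keys("all") == [r.key for r in ledger.rows]

    def test_crossfile_intersection_with_copy_is_identity(
            self, bundle, bundle_schema, tmp_path):
        paths, _, _ = bundle
        t1 = read_table(paths["table"], bundle_schema, source_id="a")
        t2 = read_table(paths["table"], bundle_schema, source_id="b")
        text = FR_TEXT + "# chr@a %int chr@b : xfile\n"
        res = apply_rules([t1, t2], parse_fr(text))
        assert res.keys("xfile") == res.keys("chr", "a")

    def test_rule_composition_matches_key_set_algebra(self, bundle,
                                                      bundle_schema):
        paths, _, _ = bundle
        table = read_table(paths["table"], bundle_schema)
        text = ("BuildingPrimarykey: Chr Start End Ref Alt\n"
                "FilteringRule:\n"
                "Func.refGene %e exonic : a\n"
                "ExAC_ALL %lt 0.01 : b\n"
                "(Func.refGene %e exonic) * (ExAC_ALL %lt 0.01) : both\n"
                "(Func.refGene %e exonic) | (ExAC_ALL %lt 0.01) : either\n"
                "# a %int b : i\n# a %uni b : u\n")
        res = apply_rules([table], parse_fr(text))
        assert set(res.keys("both")) == set(res.keys("i"))
        assert set(res.keys("either")) == set(res.keys("u"))

    def test_monotone_in_numeric_threshold(self, bundle, bundle_schema):
        paths, _, _ = bundle
        table = read_table(paths["table"], bundle_schema)
        previous = None
        for c in (0.1, 0.01, 0.001, 0.0001):
            rs = parse_fr("BuildingPrimarykey: Chr Start End Ref Alt\n"
                          f"FilteringRule:\nExAC_ALL %lt {c} : r\n")
            keys = set(apply_rules([table], rs).keys("r"))
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_bind_error_reported_before_evaluation(self, bundle,
                                                   bundle_schema):
        paths, _, _ = bundle
        table = read_table(paths["table"], bundle_schema)
        rs = parse_fr("BuildingPrimarykey: Chr\nFilteringRule:\n"
                      "NoSuchField %e 1 : r\n")
        with pytest.raises(RuleError, match="NoSuchField"):
            apply_rules([table], rs)


class TestOracleEquivalence:
    def test_random_expressions_match_naive_oracle(self, tmp_path):
        """Engine vs brute-force row-by-row oracle on random tables and
        random depth-≤4 expressions over all 8 comparison operators."""
        schema = parse_fd(FD_TEXT)
        for trial in range(60):
            rng = random.Random(9000 + trial)
            rows = random_table(rng, max_rows=80)
            path = tmp_path / f"t{trial}.tsv"
            path.write_text(serialize_rows(rows))
            table = read_table(path, schema)
            ast = random_expr(rng, depth=4)
            fr = ("BuildingPrimarykey: Idx\nFilteringRule:\n"
                  f"{render_expr(ast)} : r\n")
            res = apply_rules([table], parse_fr(fr))
            assert res.keys("r") == oracle_matching_keys(ast, rows), \
                render_expr(ast)
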