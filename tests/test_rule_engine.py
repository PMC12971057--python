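import random

import pytest

from metallomine.io_formats import DomainHit
from metallomine.rule_engine import (
    And,
    CdsScope,
    Identifier,
    Not,
    Or,
    RuleSyntaxError,
    apply_cutoffs,
    default_rule,
    evaluate,
    list_identifiers,
    parse_rule,
    pretty,
)

from conftest import brute_force, random_assignment, random_ast


class TestParser:
    def test_cds_scope(self):
        ast = parse_rule("cds(Condensation and AMP-binding)")
        assert ast == CdsScope(And(Identifier("Condensation"),
                                   Identifier("AMP-binding")))

    def test_precedence_not_over_and_over_or(self):
        ast = parse_rule("A or B and not C")
        assert ast == Or(Identifier("A"),
                         And(Identifier("B"), Not(Identifier("C"))))

    def test_left_associativity(self):
        assert parse_rule("A or B or C") == Or(Or(Identifier("A"),
                                                  Identifier("B")),
                                               Identifier("C"))

    def test_nested_cds_rejected(self):
        with pytest.raises(RuleSyntaxError, match="nested"):
            parse_rule("cds(A or cds(B))")

    @pytest.mark.parametrize(
        "text,match",
        [
            ("(A or B", "end of expression"),
            ("A or B)", "trailing"),
            ("", "empty"),
            ("A %% B", "unknown token"),
            ("A or", "end of expression"),
            ("and A", "unexpected"),
        ],
    )
    def test_syntax_errors_carry_position(self, text, match):
        with pytest.raises(RuleSyntaxError, match=match) as exc:
            parse_rule(text)
        assert "position" in str(exc.value)

    def test_canonical_rule_top_level_disjuncts(self, rule):
        # Or chain, leftmost disjuncts are the standalone NRPS-domain markers
        assert isinstance(rule, Or)
        left = rule.left
        assert left == Or(Identifier("VibH_like"), Identifier("Cy_tandem"))
        # the other branch requires the single-gene core-domain pair
        assert isinstance(rule.right, And)
        assert isinstance(rule.right.left, CdsScope)

    def test_comments_and_newlines_insignificant(self):
        ast = parse_rule("# leading comment\nA and  # trailing\n B")
        assert ast == And(Identifier("A"), Identifier("B"))

    @pytest.mark.parametrize("text", [
        "cds(Condensation and AMP-binding)",
        "A or B and not C",
        "not not MetRS-like",
        "cds(A or B) and not (C or D)",
    ])
    def test_pretty_round_trip_fixture_rules(self, text):
        ast = parse_rule(text)
        assert parse_rule(pretty(ast)) == ast

    def test_pretty_round_trip_canonical_and_random_rules(self, rule):
        assert parse_rule(pretty(rule)) == rule
        rng = random.Random(20)
        idents = ["A", "B-1", "C_x", "D", "E2"]
        for _ in range(200):
            ast = random_ast(rng, idents, depth=4)
            assert parse_rule(pretty(ast)) == ast


class TestApplyCutoffs:
    def test_below_cutoff_removed_and_boundary_inclusive(self, registry):
        hits = [
            DomainHit("g1", "EntA", 100.0),   # cutoff 200 -> removed
            DomainHit("g1", "EntA", 200.0),   # == cutoff -> kept
            DomainHit("g2", "EntC", 299.9),   # cutoff 300 -> removed
        ]
        sig = apply_cutoffs(hits, registry)
        assert sig == {"g1": {"EntA"}}

    def test_unknown_profile_is_an_error(self, registry):
        with pytest.raises(KeyError, match="NotAProfile"):
            apply_cutoffs([DomainHit("g1", "NotAProfile", 999.0)], registry)

    def test_grouping_preserves_all_surviving_profiles(self, registry):
        hits = [
            DomainHit("g1", "Condensation", 50.0),
            DomainHit("g1", "AMP-binding", 50.0),
            DomainHit("g2", "EntA", 500.0),
        ]
        sig = apply_cutoffs(hits, registry)
        assert sig == {"g1": {"Condensation", "AMP-binding"}, "g2": {"EntA"}}


def _core_gene():
    return {"Condensation", "AMP-binding"}


class TestEvaluateCanonicalRule:
    def test_catechol_branch_fires(self, rule):
        hits = {"g1": {"EntA"}, "g2": {"EntC"}, "g3": _core_gene()}
        verdict = evaluate(rule, hits)
        assert verdict.satisfied
        assert {"EntA", "EntC"} <= verdict.triggering_identifiers

    def test_hydroxamate_branch_vetoed_by_ktzt(self, rule):
        hits = {"g1": {"Orn_monoox"}, "g2": {"KtzT"}, "g3": _core_gene()}
        verdict = evaluate(rule, hits)
        assert not verdict.satisfied
        assert verdict.triggering_identifiers == frozenset()

    def test_standalone_marker_fires_without_nrps_core(self, rule):
        assert evaluate(rule, {"g1": {"VibH_like"}}).satisfied

    def test_core_domains_on_separate_genes_fail_cds_scope(self, rule):
        hits = {
            "g1": {"Condensation"},
            "g2": {"AMP-binding"},
            "g3": {"EntA"},
            "g4": {"EntC"},
        }
        assert not evaluate(rule, hits).satisfied

    def test_empty_region_not_satisfied(self, rule):
        assert not evaluate(rule, {}).satisfied

    def test_ibh_asp_vetoed_by_sbh_asp(self, rule):
        hits = {"g1": {"IBH_Asp"}, "g2": {"SBH_Asp"}, "g3": _core_gene()}
        assert not evaluate(rule, hits).satisfied
        hits.pop("g2")
        assert evaluate(rule, hits).satisfied

    def test_negative_constraint_is_region_scoped(self, rule):
        # KtzT on a different gene still vetoes the ornithine branch
        hits = {"g1": {"Orn_monoox", "KtzT"}, "g3": _core_gene()}
        assert not evaluate(rule, hits).satisfied
        hits2 = {"g1": {"Orn_monoox"}, "far_away_gene": {"KtzT"},
                 "g3": _core_gene()}
        assert not evaluate(rule, hits2).satisfied


class TestListIdentifiers:
    def test_canonical_rule_negated_set(self, rule):
        _, negated = list_identifiers(rule)
        assert negated == {"SBH_Asp", "KtzT", "MetRS-like"}

    def test_single_identifier(self):
        assert list_identifiers(parse_rule("A")) == ({"A"}, set())

    def test_double_negation_is_positive(self):
        # even number of nots -> positive polarity (matches the truth-table
        # oracle: not not A == A)
        ast = parse_rule("not not A")
        assert list_identifiers(ast) == ({"A"}, set())
        assert evaluate(ast, {"g": {"A"}}).satisfied is brute_force(ast, {"g": {"A"}})


class TestProperties:
    def test_truth_table_equivalence_with_brute_force(self, rule):
        rng = random.Random(11)
        idents = [f"P{i}" for i in range(12)]
        checked = 0
        for _ in range(120):
            ast = random_ast(rng, idents, depth=4)
            for _ in range(6):
                assignment = random_assignment(rng, idents)
                assert evaluate(ast, assignment).satisfied == brute_force(
                    ast, assignment
                )
                checked += 1
        assert checked >= 500

    def test_canonical_rule_agrees_with_brute_force(self, rule):
        rng = random.Random(5)
        idents = sorted(set.union(*map(set, list_identifiers(rule))))
        for _ in range(300):
            assignment = random_assignment(rng, idents)
            assert evaluate(rule, assignment).satisfied == brute_force(
                rule, assignment
            )

    def test_monotonicity_in_positive_and_negated_profiles(self, rule):
        rng = random.Random(42)
        positive, negated = list_identifiers(rule)
        pos_only = sorted(positive - negated)
        neg_only = sorted(negated - positive)
        idents = sorted(positive | negated)
        for _ in range(200):
            assignment = random_assignment(rng, idents)
            before = evaluate(rule, assignment).satisfied
            target_gene = rng.choice(sorted(assignment))
            grown = {g: set(p) for g, p in assignment.items()}
            if before:
                # adding a positive-only profile never flips true -> false
                grown[target_gene].add(rng.choice(pos_only))
                assert evaluate(rule, grown).satisfied
            else:
                # adding a negated-only profile never flips false -> true
                grown[target_gene].add(rng.choice(neg_only))
                assert not evaluate(rule, grown).satisfied

    def test_triggering_identifiers_empty_iff_unsatisfied(self):
        rng = random.Random(3)
        idents = ["A", "B", "C", "D"]
        for _ in range(200):
            ast = random_ast(rng, idents, depth=3)
            assignment = random_assignment(rng, idents)
            verdict = evaluate(ast, assignment)
            if not verdict.satisfied:
                assert verdict.triggering_identifiers == frozenset()
            else:
                positive, _ = list_identifiers(ast)
                assert verdict.triggering_identifiers <= positive
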