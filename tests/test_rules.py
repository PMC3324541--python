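"""Truth tables, Boolean minimization, occurrence and rule grouping."""

from itertools import combinations, product

import numpy as np
import pytest

from ionrules import (canonical_dnf, cross_type_consistency, minimize_boolean,
                      rule_occurrence, truth_table)
from ionrules.logic import evaluate, parse_formula
from ionrules.rules import LogicRule

from conftest import make_record


def hcn3_kv14_records(panel5):
    """The nine-neuron pattern behind the Kv1.4 = HCN3 rule: three neurons
    express both genes, five express neither, one expresses the target
    without its input."""
    rows = [(1, 1)] * 3 + [(0, 0)] * 5 + [(0, 1)]
    return [make_record(i, layer="L5", morph="MC", etype="cAD",
                        bits=(kv, h3, 0, 0, 0))
            for i, (h3, kv) in enumerate(rows)]


class TestTruthTable:
    def test_nine_neuron_pattern(self, panel5):
        records = hcn3_kv14_records(panel5)
        table = truth_table(records, "Kv1.4", ["HCN3"], panel5)
        assert table == {(1,): (3, 0), (0,): (1, 5)}

    def test_identical_records_give_single_row(self, panel5):
        records = [make_record(i, bits=(1, 0, 1, 0, 0)) for i in range(6)]
        table = truth_table(records, "Kv1.4", ["HCN3", "Kv3.1"], panel5)
        assert table == {(0, 1): (6, 0)}

    def test_counts_sum_to_neuron_count(self, panel5):
        rng = np.random.default_rng(0)
        records = [make_record(i, bits=tuple(rng.integers(0, 2, 5)))
                   for i in range(25)]
        table = truth_table(records, "Kv1.4", ["HCN3", "HCN1"], panel5)
        assert sum(n1 + n0 for n1, n0 in table.values()) == 25


class TestMinimizeBoolean:
    def test_identity_rule_from_nine_neuron_pattern(self, panel5):
        formula = minimize_boolean({(1,): (3, 0), (0,): (1, 5)},
                                   ["HCN3"], panel5)
        assert formula.text() == "HCN3"

    def test_all_rows_on_gives_constant_true(self, panel5):
        formula = minimize_boolean({(0,): (4, 0), (1,): (3, 1)},
                                   ["HCN3"], panel5)
        assert formula.is_true

    def test_all_tied_rows_give_no_rule(self, panel5):
        assert minimize_boolean({(0,): (2, 2), (1,): (1, 1)},
                                ["HCN3"], panel5) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_minimal_dnf(self, seed):
        """On random 3-input tables the minimized formula agrees with the
        majority label on every decided row and has the minimum literal
        count over all DNFs (exhaustively enumerated)."""
        from ionrules import GenePanel
        panel = GenePanel(("X", "Y", "Z", "W"))
        rng = np.random.default_rng(seed)
        table = {}
        for bits in product((0, 1), repeat=3):
            if rng.random() < 0.7:  # leave some rows unobserved
                table[bits] = (int(rng.integers(0, 4)), int(rng.integers(0, 4)))
        if not table:
            table[(0, 0, 0)] = (1, 0)
        formula = minimize_boolean(table, ["X", "Y", "Z"], panel)
        onset = {b for b, (n1, n0) in table.items() if n1 > n0}
        offset = {b for b, (n1, n0) in table.items() if n0 > n1}
        if not onset and not offset:
            assert formula is None
            return
        # agreement with the majority label on every decided row
        for bits in onset | offset:
            value = formula.evaluate(dict(zip("XYZ", bits)))
            assert value is (bits in onset)
        # literal-count minimality vs exhaustive DNF enumeration
        lits = [("X", True), ("X", False), ("Y", True), ("Y", False),
                ("Z", True), ("Z", False)]
        clauses = []
        for r in (1, 2, 3):
            for combo in combinations(lits, r):
                if len({g for g, _ in combo}) == r:
                    clauses.append(combo)

        def consistent(dnf_clauses):
            for bits in onset | offset:
                env = dict(zip("XYZ", bits))
                val = any(all((env[g] == 1) is pos for g, pos in cl)
                          for cl in dnf_clauses)
                if val is not (bits in onset):
                    return False
            return True

        best = None
        if not onset:
            best = 0  # constant FALSE
        elif not offset:
            best = 0  # constant TRUE
        else:
            for n_cl in (1, 2, 3, 4):
                for combo in combinations(clauses, n_cl):
                    if consistent(combo):
                        count = sum(len(c) for c in combo)
                        best = count if best is None else min(best, count)
                if best is not None:
                    break
        assert formula.n_literals() == best


class TestOccurrence:
    def test_nine_neuron_rule_holds_eight_of_nine(self, panel5):
        records = hcn3_kv14_records(panel5)
        formula = canonical_dnf("HCN3", order_key=panel5.order_key)
        assert rule_occurrence(formula, "Kv1.4", records, panel5) == (8, 9)

    def test_constant_true_on_all_one_target(self, panel5):
        records = [make_record(i, bits=(1, 1, 0, 1, 0)) for i in range(5)]
        formula = canonical_dnf("TRUE")
        assert rule_occurrence(formula, "Kv1.4", records, panel5) == (5, 5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_neuron_oracle(self, panel5, seed):
        rng = np.random.default_rng(seed)
        records = [make_record(i, bits=tuple(rng.integers(0, 2, 5)))
                   for i in range(20)]
        text = "HCN3 AND NOT Kv3.1 OR HCN1"
        formula = canonical_dnf(text, order_key=panel5.order_key)
        ast = parse_formula(text)
        expected = sum(
            1 for r in records
            if int(evaluate(ast, {"HCN3": r.expression[1],
                                  "Kv3.1": r.expression[2],
                                  "HCN1": r.expression[4]}))
            == r.expression[0])
        assert rule_occurrence(formula, "Kv1.4", records, panel5) == \
            (expected, 20)


class TestConsistencyGrouping:
    def _rule(self, target, text, lme):
        return LogicRule(target=target, formula=canonical_dnf(text),
                         types_observed=(lme,), n_match=5, n_total=5)

    def test_same_formula_in_three_types_forms_one_group(self):
        rules = [self._rule("HCN3", "Caβ1", t) for t in
                 (("L2/3", "LBC", "dFS"), ("L4", "MC", "cAD"),
                  ("L5", "MC", "cAD"))]
        groups = cross_type_consistency(rules)
        assert len(groups) == 1
        assert groups[0]["consistent"] and not groups[0]["conflicting"]
        assert len(groups[0]["types"]) == 3

    def test_equivalent_syntax_merges(self):
        a = self._rule("Kv1.2", "Kv3.1 AND Kv3.2", ("L4", "LBC", "cST"))
        b = self._rule("Kv1.2", "Kv3.2 AND Kv3.1 AND (Kv3.1 OR Kv3.2)",
                       ("L5", "MC", "cAD"))
        groups = cross_type_consistency([a, b])
        assert len(groups) == 1 and groups[0]["consistent"]

    def test_contradictory_rules_stay_distinct_and_flagged(self):
        a = self._rule("HCN2", "Kv3.1 AND Kv2.2 AND NOT Kv4.3",
                       ("L2/3", "LBC", "cAD"))
        b = self._rule("HCN2", "NOT Kv3.1 AND NOT Kv2.2 AND NOT Kv4.3",
                       ("L5", "MC", "cAD"))
        groups = cross_type_consistency([a, b])
        assert len(groups) == 2
        assert all(g["conflicting"] for g in groups)
        assert not any(g["consistent"] for g in groups)
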