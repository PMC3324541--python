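"""Boolean expression-rule extraction per neuronal type.

Within an LME type where the gene-augmented model beats the LME-only model,
the target gene's observed values are tabulated against the selected input
genes' observed on/off combinations. The majority target label per observed
combination defines the on-set; tied and unobserved combinations are
don't-cares; Quine–McCluskey minimization then yields a compact AND/OR/NOT
rule, e.g. ``Kv1.4 = HCN3`` or ``Kv1.2 = Kv3.1 AND Kv3.2``. A rule's
*occurrence* — how many neurons of the type obey it — quantifies its
support; rules below the occurrence threshold are reported separately
rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import EvalResult
from .data import NeuronRecord
from .isvm import ISVMModel
from .panel import GenePanel
from .logic import Dnf, dnf_from_bitmap, canonical_dnf

__all__ = ["LogicRule", "ExtractionResult", "candidate_types", "truth_table",
           "minimize_boolean", "rule_occurrence", "extract_rules",
           "cross_type_consistency", "write_rules_tsv", "write_rules_json"]

LMEKey = tuple[str, str, str]


@dataclass(frozen=True)
class LogicRule:
    target: str
    formula: Dnf
    types_observed: tuple[LMEKey, ...]
    n_match: int
    n_total: int
    #: selected inputs that were constant within the type and hence dropped
    dropped_inputs: tuple[tuple[str, int], ...] = ()

    @property
    def occurrence(self) -> float:
        return self.n_match / self.n_total if self.n_total else 0.0

    def text(self) -> str:
        return f"{self.target} = {self.formula.text()}"


@dataclass(frozen=True)
class ExtractionResult:
    rules: tuple[LogicRule, ...]
    sub_threshold: tuple[LogicRule, ...]

    def __iter__(self):
        return iter(self.rules)


def candidate_types(
    records: Sequence[NeuronRecord],
    model: ISVMModel,
    base_result: EvalResult,
    isvm_result: EvalResult,
) -> list[LMEKey]:
    """LME types where the gene-augmented model strictly beats the base.

    Compared on held-out per-type accuracy; types absent from either
    result are skipped. Output order follows first appearance in records.
    """
    seen: list[LMEKey] = []
    for r in records:
        if r.lme not in seen:
            seen.append(r.lme)
    out = []
    for key in seen:
        base_acc = base_result.per_type_accuracy.get(key)
        isvm_acc = isvm_result.per_type_accuracy.get(key)
        if base_acc is not None and isvm_acc is not None and isvm_acc > base_acc:
            out.append(key)
    return out


def truth_table(
    records_of_type: Sequence[NeuronRecord],
    target: str,
    inputs: Sequence[str],
    panel: GenePanel,
) -> dict[tuple[int, ...], tuple[int, int]]:
    """Observed input-combination → (n with target=1, n with target=0)."""
    if not inputs:
        raise ValueError("need at least one input gene")
    if not records_of_type:
        raise ValueError("need at least one record")
    t_idx = panel.index(target)
    in_idx = [panel.index(g) for g in inputs]
    table: dict[tuple[int, ...], tuple[int, int]] = {}
    for r in records_of_type:
        pattern = tuple(r.expression[i] for i in in_idx)
        n1, n0 = table.get(pattern, (0, 0))
        if r.expression[t_idx] == 1:
            table[pattern] = (n1 + 1, n0)
        else:
            table[pattern] = (n1, n0 + 1)
    return table


def minimize_boolean(
    table: Mapping[tuple[int, ...], tuple[int, int]],
    inputs: Sequence[str],
    panel: GenePanel | None = None,
) -> Dnf | None:
    """Minimal DNF from a truth table by majority vote per observed row.

    Rows where target=1 outnumbers target=0 form the on-set; the reverse
    the off-set; exact ties and unobserved combinations are don't-cares.
    Returns None (no rule) when every observed row is tied.
    """
    if not table:
        raise ValueError("empty truth table")
    order_key = panel.order_key if panel is not None else None
    n_bits = len(inputs)
    onset, offset = [], []
    for pattern, (n1, n0) in table.items():
        if len(pattern) != n_bits:
            raise ValueError("pattern width mismatch with inputs")
        if n1 > n0:
            onset.append(pattern)
        elif n0 > n1:
            offset.append(pattern)
    if not onset and not offset:
        return None
    from itertools import product
    observed = set(map(tuple, onset)) | set(map(tuple, offset))
    dontcares = [bits for bits in product((0, 1), repeat=n_bits)
                 if bits not in observed]
    return dnf_from_bitmap(list(inputs), onset, dontcares, order_key=order_key)


def rule_occurrence(
    formula: Dnf,
    target: str,
    records_of_type: Sequence[NeuronRecord],
    panel: GenePanel,
) -> tuple[int, int]:
    """(n_match, n_total): neurons whose target bit equals the rule's output."""
    t_idx = panel.index(target)
    genes = sorted(formula.genes())
    idx = {g: panel.index(g) for g in genes}
    n_match = 0
    for r in records_of_type:
        assignment = {g: r.expression[i] for g, i in idx.items()}
        predicted = int(formula.evaluate(assignment))
        if predicted == r.expression[t_idx]:
            n_match += 1
    return n_match, len(records_of_type)


def extract_rules(
    records: Sequence[NeuronRecord],
    models: Mapping[str, ISVMModel],
    panel: GenePanel,
    min_occurrence: float = 0.8,
) -> ExtractionResult:
    """Extract per-type Boolean rules for every modeled target gene.

    For each target with selected inputs and each candidate LME type
    (where the augmented model beat the base on held-out accuracy):
    inputs constant within the type are dropped (recorded on the rule),
    the within-type truth table is minimized, and the rule's occurrence
    computed. Rules with occurrence >= ``min_occurrence`` are retained;
    weaker ones are reported in ``sub_threshold``.
    """
    by_type: dict[LMEKey, list[NeuronRecord]] = {}
    for r in records:
        by_type.setdefault(r.lme, []).append(r)

    retained: list[LogicRule] = []
    weak: list[LogicRule] = []
    for target, model in models.items():
        if not model.selected:
            continue
        types = candidate_types(records, model, model.base_eval,
                                model.final_eval)
        for key in types:
            recs = by_type.get(key, [])
            if not recs:
                continue
            inputs, dropped = [], []
            for g in model.selected:
                vals = {r.expression[panel.index(g)] for r in recs}
                if len(vals) == 1:
                    dropped.append((g, vals.pop()))
                else:
                    inputs.append(g)
            if not inputs:
                continue
            table = truth_table(recs, target, inputs, panel)
            formula = minimize_boolean(table, inputs, panel)
            if formula is None:
                continue
            n_match, n_total = rule_occurrence(formula, target, recs, panel)
            rule = LogicRule(
                target=target, formula=formula, types_observed=(key,),
                n_match=n_match, n_total=n_total,
                dropped_inputs=tuple(dropped))
            if rule.occurrence >= min_occurrence:
                retained.append(rule)
            else:
                weak.append(rule)
    return ExtractionResult(rules=tuple(retained), sub_threshold=tuple(weak))


def cross_type_consistency(
    rules: Sequence[LogicRule],
) -> list[dict]:
    """Group rules by (target, canonical formula) across neuronal types.

    Returns one dict per (target, formula) group with keys ``target``,
    ``formula``, ``types`` and ``consistent`` (seen in >= 2 types). When a
    target carries two logically different formulas in different types the
    groups stay distinct and each is additionally marked
    ``conflicting=True``.
    """
    groups: dict[tuple[str, str], dict] = {}
    for rule in rules:
        canon = canonical_dnf(rule.formula)
        key = (rule.target, canon.text())
        entry = groups.setdefault(key, {
            "target": rule.target,
            "formula": canon,
            "types": [],
            "rules": [],
        })
        for t in rule.types_observed:
            if t not in entry["types"]:
                entry["types"].append(t)
        entry["rules"].append(rule)
    per_target: dict[str, int] = {}
    for (target, _), entry in groups.items():
        per_target[target] = per_target.get(target, 0) + 1
    out = []
    for (target, _), entry in groups.items():
        entry["consistent"] = len(entry["types"]) >= 2
        entry["conflicting"] = per_target[target] >= 2
        out.append(entry)
    return out


def write_rules_tsv(result: ExtractionResult, path: str | Path) -> None:
    lines = ["target\tlayer\tmorphology\tetype\tformula\tn_match\tn_total"
             "\tretained"]
    for retained, rules in ((True, result.rules), (False, result.sub_threshold)):
        for rule in rules:
            for key in rule.types_observed:
                lines.append("\t".join([
                    rule.target, *key, rule.formula.text(),
                    str(rule.n_match), str(rule.n_total),
                    "yes" if retained else "no"]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_rules_json(result: ExtractionResult, path: str | Path) -> None:
    def encode(rule: LogicRule, retained: bool) -> dict:
        return {
            "target": rule.target,
            "formula": rule.formula.text(),
            "clauses": [[[g, pos] for g, pos in clause]
                        for clause in rule.formula.clauses],
            "types": [list(t) for t in rule.types_observed],
            "n_match": rule.n_match,
            "n_total": rule.n_total,
            "dropped_constant_inputs": [[g, v] for g, v in rule.dropped_inputs],
            "retained": retained,
        }
    payload = ([encode(r, True) for r in result.rules]
               + [encode(r, False) for r in result.sub_threshold])
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
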