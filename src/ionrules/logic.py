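"""Boolean formulas over gene literals: parse, evaluate, canonicalize.

Rules are written in a small grammar — ``A AND NOT B OR C``, with
parentheses, case-insensitive keywords ``AND``/``OR``/``NOT``/``TRUE``/
``FALSE``, and any other token taken as a gene symbol. ``NOT`` binds
tightest, then ``AND``, then ``OR``.

The canonical form is a minimal disjunctive normal form (DNF) obtained by
enumerating the formula's full truth table and re-minimizing with the
Quine–McCluskey procedure (sympy's SOPform), then ordering literals within
clauses and clauses among themselves by a stable gene order. Logically
equivalent formulas therefore canonicalize to the identical object, and
genes with no influence drop out.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Mapping, Sequence

import sympy
from sympy.logic import SOPform

__all__ = ["Formula", "Dnf", "parse_formula", "format_formula", "evaluate",
           "variables", "canonical_dnf", "dnf_from_bitmap", "TRUE", "FALSE"]

# Formula AST: ("lit", gene, positive) | ("and", [args]) | ("or", [args])
#              | ("not", arg) | ("const", bool)
Formula = tuple

TRUE: Formula = ("const", True)
FALSE: Formula = ("const", False)

_KEYWORDS = {"AND", "OR", "NOT", "TRUE", "FALSE", "(", ")"}


def _tokenize(text: str) -> list[str]:
    out: list[str] = []
    for raw in text.replace("(", " ( ").replace(")", " ) ").split():
        up = raw.upper()
        out.append(up if up in _KEYWORDS else raw)
    return out


def parse_formula(text: str) -> Formula:
    """Parse rule text into a formula AST; raises ValueError on bad syntax."""
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of formula")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValueError(f"expected {expected!r}, found {tok!r}")
        pos += 1
        return tok

    def parse_or() -> Formula:
        terms = [parse_and()]
        while peek() == "OR":
            take("OR")
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and() -> Formula:
        factors = [parse_not()]
        while peek() == "AND":
            take("AND")
            factors.append(parse_not())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_not() -> Formula:
        if peek() == "NOT":
            take("NOT")
            return ("not", parse_not())
        return parse_atom()

    def parse_atom() -> Formula:
        tok = take()
        if tok == "(":
            inner = parse_or()
            take(")")
            return inner
        if tok == "TRUE":
            return TRUE
        if tok == "FALSE":
            return FALSE
        if tok in (")", "AND", "OR"):
            raise ValueError(f"unexpected token {tok!r}")
        return ("lit", tok, True)

    result = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens: {tokens[pos:]}")
    return result


def evaluate(formula: Formula, assignment: Mapping[str, int]) -> bool:
    """Evaluate under a gene → 0/1 (or bool) assignment."""
    op = formula[0]
    if op == "const":
        return bool(formula[1])
    if op == "lit":
        value = bool(assignment[formula[1]])
        return value if formula[2] else not value
    if op == "not":
        return not evaluate(formula[1], assignment)
    if op == "and":
        return all(evaluate(f, assignment) for f in formula[1])
    if op == "or":
        return any(evaluate(f, assignment) for f in formula[1])
    raise ValueError(f"bad formula node {op!r}")


def variables(formula: Formula) -> set[str]:
    op = formula[0]
    if op == "const":
        return set()
    if op == "lit":
        return {formula[1]}
    if op == "not":
        return variables(formula[1])
    return set().union(*(variables(f) for f in formula[1]))


@dataclass(frozen=True)
class Dnf:
    """Canonical minimal DNF: OR of AND-clauses of signed gene literals.

    ``clauses`` is a tuple of clauses; each clause a tuple of
    ``(gene, positive)`` literals. The constants are the empty-OR
    (``clauses == ()`` → FALSE) and the empty-AND singleton
    (``clauses == ((),)`` → TRUE).
    """

    clauses: tuple[tuple[tuple[str, bool], ...], ...]

    @property
    def is_false(self) -> bool:
        return len(self.clauses) == 0

    @property
    def is_true(self) -> bool:
        return self.clauses == ((),)

    def text(self) -> str:
        if self.is_false:
            return "FALSE"
        if self.is_true:
            return "TRUE"
        parts = []
        for clause in self.clauses:
            lits = [(g if pos else f"NOT {g}") for g, pos in clause]
            parts.append(" AND ".join(lits))
        return " OR ".join(parts)

    def to_formula(self) -> Formula:
        if self.is_false:
            return FALSE
        if self.is_true:
            return TRUE
        terms: list[Formula] = []
        for clause in self.clauses:
            lits: list[Formula] = [("lit", g, pos) for g, pos in clause]
            terms.append(lits[0] if len(lits) == 1 else ("and", lits))
        return terms[0] if len(terms) == 1 else ("or", terms)

    def evaluate(self, assignment: Mapping[str, int]) -> bool:
        return evaluate(self.to_formula(), assignment)

    def genes(self) -> set[str]:
        return {g for clause in self.clauses for g, _ in clause}

    def n_literals(self) -> int:
        return sum(len(c) for c in self.clauses)

    def __str__(self) -> str:
        return self.text()


def format_formula(formula: Formula) -> str:
    """Render an AST back to rule text (fully parenthesized where needed)."""
    op = formula[0]
    if op == "const":
        return "TRUE" if formula[1] else "FALSE"
    if op == "lit":
        return formula[1] if formula[2] else f"NOT {formula[1]}"
    if op == "not":
        return f"NOT ({format_formula(formula[1])})"
    joiner = " AND " if op == "and" else " OR "
    return joiner.join(f"({format_formula(f)})" for f in formula[1])


def _sympy_to_dnf(expr, order_key: Callable[[str], object]) -> Dnf:
    if expr is sympy.true:
        return Dnf(clauses=((),))
    if expr is sympy.false:
        return Dnf(clauses=())

    def clause_literals(term) -> tuple[tuple[str, bool], ...]:
        lits = term.args if isinstance(term, sympy.And) else (term,)
        out = []
        for lit in lits:
            if isinstance(lit, sympy.Not):
                out.append((str(lit.args[0]), False))
            else:
                out.append((str(lit), True))
        return tuple(sorted(out, key=lambda lt: (order_key(lt[0]), not lt[1])))

    terms = expr.args if isinstance(expr, sympy.Or) else (expr,)
    clauses = tuple(sorted(
        (clause_literals(t) for t in terms),
        key=lambda c: tuple((order_key(g), not pos) for g, pos in c)))
    return Dnf(clauses=clauses)


def dnf_from_bitmap(
    genes: Sequence[str],
    minterms: Sequence[Sequence[int]],
    dontcares: Sequence[Sequence[int]] = (),
    order_key: Callable[[str], object] | None = None,
) -> Dnf:
    """Minimal DNF from explicit on-set / don't-care bit patterns.

    ``minterms``/``dontcares`` are bit tuples aligned to ``genes``.
    Minimization is Quine–McCluskey with don't-cares (sympy SOPform); the
    result is normalized with literal and clause order given by
    ``order_key`` (default: ``genes`` order, then name).
    """
    if order_key is None:
        base = {g: i for i, g in enumerate(genes)}
        order_key = lambda g: (base.get(g, len(base)), g)  # noqa: E731
    if not minterms:
        return Dnf(clauses=())
    syms = [sympy.Symbol(g) for g in genes]
    expr = SOPform(syms, [list(m) for m in minterms],
                   [list(d) for d in dontcares] or None)
    return _sympy_to_dnf(expr, order_key)


def canonical_dnf(
    formula: Formula | Dnf | str,
    order_key: Callable[[str], object] | None = None,
) -> Dnf:
    """Canonical minimal DNF of any formula (text, AST or Dnf).

    Enumerates the full truth table over the formula's variables, then
    re-minimizes; equivalent formulas map to the identical ``Dnf`` and
    non-influential variables disappear. Variable enumeration order is
    ``order_key`` (default alphabetical), which also orders the output.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if isinstance(formula, Dnf):
        formula = formula.to_formula()
    if order_key is None:
        order_key = lambda g: g  # noqa: E731
    vars_sorted = sorted(variables(formula), key=order_key)
    if not vars_sorted:
        return Dnf(clauses=((),) if evaluate(formula, {}) else ())
    minterms = []
    for bits in product((0, 1), repeat=len(vars_sorted)):
        if evaluate(formula, dict(zip(vars_sorted, bits))):
            minterms.append(bits)
    return dnf_from_bitmap(vars_sorted, minterms, order_key=order_key)
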