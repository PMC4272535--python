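"""Recursive-descent parser for PBLSTL specification text.

The concrete grammar is documented in ``docs/grammar.ebnf`` (shipped with
the package).  Specifications are UTF-8 text, whitespace-insensitive, with
``#`` line comments and one or more top-level statements of the form
``P >= 0.9 [ ... ]``.
"""

from __future__ import annotations

import re

from ..errors import PblstlSemanticError, PblstlSyntaxError
from ..stml import MEASURE_NAMES
from . import ast

UNARY_FUNCTIONS = {"abs", "ceil", "floor", "round", "sign", "sqrt", "trunc"}
BINARY_FUNCTIONS = {"add", "subtract", "multiply", "divide", "power", "min", "max"}
STAT_SIMPLE = {"mean", "median", "mode", "min", "max", "sum", "stdev"}
COLLECTION_KEYWORDS = {"regions", "clusters", "filter"}

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<number>\d+\.\d*|\.\d+|\d+)
  | (?P<statevar>\{[^}{]*\})
  | (?P<op><=>|=>|<=|>=|[<>=()\[\],^&|~!-])
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    """,
    re.VERBOSE,
)


class _Token:
    __slots__ = ("kind", "text", "line", "column")

    def __init__(self, kind, text, line, column):
        self.kind = kind
        self.text = text
        self.line = line
        self.column = column

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Token({self.kind}, {self.text!r})"


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos = 0
    line, col = 1, 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise PblstlSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            tokens.append(_Token(kind, value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(_Token("eof", "", line, col))
    return tokens


class _Parser:
    """One-token-lookahead recursive descent over the token stream."""

    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def error(self, expected: str):
        tok = self.cur
        shown = tok.text or "end of input"
        raise PblstlSyntaxError(f"expected {expected}, found {shown!r}",
                                tok.line, tok.column)

    def accept(self, text: str) -> bool:
        if self.cur.text == text and self.cur.kind in ("op", "name"):
            self.i += 1
            return True
        return False

    def expect(self, text: str):
        if not self.accept(text):
            self.error(repr(text))

    def number(self) -> float:
        neg = self.accept("-")
        if self.cur.kind != "number":
            self.error("a number")
        value = float(self.cur.text)
        self.i += 1
        return -value if neg else value

    # --- statements --------------------------------------------------------

    def specification(self) -> list[ast.PblstlStatement]:
        statements = []
        while self.cur.kind != "eof":
            statements.append(self.statement())
        if not statements:
            raise PblstlSemanticError("specification contains no statements")
        return statements

    def statement(self) -> ast.PblstlStatement:
        start = self.i
        self.expect("P")
        if self.cur.text in ("<", "<=", ">", ">="):
            comparator = self.cur.text
            self.i += 1
        else:
            self.error("a probability comparator (<, <=, >, >=)")
        threshold = self.number()
        if not (0.0 < threshold < 1.0):
            raise PblstlSemanticError(
                f"probability threshold must lie strictly in (0, 1), got {threshold}"
            )
        self.expect("[")
        formula = self.formula()
        self.expect("]")
        source = " ".join(t.text for t in self.tokens[start:self.i])
        return ast.PblstlStatement(comparator=comparator, threshold=threshold,
                                   formula=formula, source=source)

    # --- Boolean / temporal grammar ----------------------------------------

    def formula(self, in_filter: bool = False) -> ast.FormulaNode:
        node = self.implication(in_filter)
        while self.accept("<=>"):
            node = ast.BinaryBoolean("equiv", node, self.implication(in_filter))
        return node

    def implication(self, in_filter: bool) -> ast.FormulaNode:
        left = self.until_level(in_filter)
        if self.accept("=>"):
            return ast.BinaryBoolean("implies", left, self.implication(in_filter))
        return left

    def until_level(self, in_filter: bool) -> ast.FormulaNode:
        left = self.disjunction(in_filter)
        if self.cur.text == "U" and self.cur.kind == "name":
            if in_filter:
                raise PblstlSemanticError(
                    "temporal operators are not allowed inside filter constraints"
                )
            self.i += 1
            low, high = self.bounds()
            right = self.disjunction(in_filter)
            return ast.Until(low, high, left, right)
        return left

    def disjunction(self, in_filter: bool) -> ast.FormulaNode:
        node = self.conjunction(in_filter)
        while self.cur.text in ("V", "|"):
            self.i += 1
            node = ast.BinaryBoolean("or", node, self.conjunction(in_filter))
        return node

    def conjunction(self, in_filter: bool) -> ast.FormulaNode:
        node = self.unary_formula(in_filter)
        while self.cur.text in ("^", "&"):
            self.i += 1
            node = ast.BinaryBoolean("and", node, self.unary_formula(in_filter))
        return node

    def bounds(self) -> tuple[float, float]:
        self.expect("[")
        low = self.number()
        self.expect(",")
        high = self.number()
        self.expect("]")
        if low < 0 or high < low:
            raise PblstlSemanticError(
                f"temporal bounds must satisfy 0 <= a <= b, got [{low}, {high}]"
            )
        return low, high

    def unary_formula(self, in_filter: bool) -> ast.FormulaNode:
        if self.cur.text in ("~", "!"):
            self.i += 1
            return ast.Not(self.unary_formula(in_filter))
        if self.cur.kind == "name" and self.cur.text in ("F", "G", "X"):
            if in_filter:
                raise PblstlSemanticError(
                    "temporal operators are not allowed inside filter constraints"
                )
            op = self.cur.text
            self.i += 1
            if op == "X":
                self.expect("[")
                steps = self.number()
                self.expect("]")
                if steps != int(steps) or steps < 1:
                    raise PblstlSemanticError(
                        f"X requires a positive integer step count, got {steps}"
                    )
                return ast.Next(int(steps), self.unary_formula(in_filter))
            low, high = self.bounds()
            child = self.unary_formula(in_filter)
            return ast.Future(low, high, child) if op == "F" \
                else ast.Globally(low, high, child)
        if self.accept("("):
            node = self.formula(in_filter)
            self.expect(")")
            return node
        return self.comparison(in_filter)

    def comparison(self, in_filter: bool) -> ast.FormulaNode:
        left = self.numeric(in_filter)
        if self.cur.text in ("<", "<=", "=", ">=", ">"):
            op = self.cur.text
            self.i += 1
        else:
            self.error("a comparison operator (<, <=, =, >=, >)")
        right = self.numeric(in_filter)
        return ast.Comparison(left, op, right)

    # --- numeric grammar ----------------------------------------------------

    def numeric(self, in_filter: bool) -> ast.NumericNode:
        tok = self.cur
        if tok.kind == "number" or tok.text == "-":
            return ast.Constant(self.number())
        if tok.kind == "statevar":
            if in_filter:
                raise PblstlSemanticError(
                    "filter constraints range over spatial measures only; "
                    f"numeric state variable {tok.text} is not allowed"
                )
            self.i += 1
            name = tok.text[1:-1].strip()
            if not name:
                raise PblstlSemanticError("empty numeric state variable name {}")
            return ast.StateVariable(name)
        if tok.kind != "name":
            self.error("a numeric expression")
        name = tok.text

        if name == "d":
            self.i += 1
            self.expect("(")
            child = self.numeric(in_filter)
            self.expect(")")
            return ast.Difference(child)
        if name == "count":
            self.i += 1
            self.expect("(")
            coll = self.collection(in_filter)
            self.expect(")")
            return ast.Statistic("count", coll)
        if name == "percentile":
            self.i += 1
            self.expect("(")
            coll = self.collection(in_filter)
            self.expect(",")
            measure = self.measure_name()
            self.expect(",")
            q = self.number()
            self.expect(")")
            if not (0.0 <= q <= 100.0):
                raise PblstlSemanticError(
                    f"percentile rank must lie in [0, 100], got {q}"
                )
            return ast.Statistic("percentile", coll, measure=measure, q=q)
        if name == "covariance":
            self.i += 1
            self.expect("(")
            coll1 = self.collection(in_filter)
            self.expect(",")
            m1 = self.measure_name()
            self.expect(",")
            coll2 = self.collection(in_filter)
            self.expect(",")
            m2 = self.measure_name()
            self.expect(")")
            return ast.Statistic("covariance", coll1, measure=m1,
                                 collection2=coll2, measure2=m2)
        if name in STAT_SIMPLE | BINARY_FUNCTIONS | UNARY_FUNCTIONS:
            self.i += 1
            self.expect("(")
            # min/max are statistics when applied to a collection, arithmetic
            # otherwise; dispatch on the first argument
            if name in STAT_SIMPLE and self.cur.text in COLLECTION_KEYWORDS:
                coll = self.collection(in_filter)
                self.expect(",")
                measure = self.measure_name()
                self.expect(")")
                return ast.Statistic(name, coll, measure=measure)
            if name in UNARY_FUNCTIONS:
                child = self.numeric(in_filter)
                self.expect(")")
                return ast.UnaryFunction(name, child)
            if name in BINARY_FUNCTIONS:
                left = self.numeric(in_filter)
                self.expect(",")
                right = self.numeric(in_filter)
                self.expect(")")
                return ast.BinaryFunction(name, left, right)
        if in_filter and name in MEASURE_NAMES:
            self.i += 1
            return ast.MeasureRef(name)
        if name in MEASURE_NAMES:
            raise PblstlSemanticError(
                f"spatial measure {name!r} can only be referenced inside a "
                "filter constraint or through a statistical function"
            )
        self.error("a numeric expression")

    def measure_name(self) -> str:
        if self.cur.kind == "name" and self.cur.text in MEASURE_NAMES:
            name = self.cur.text
            self.i += 1
            return name
        self.error(f"a spatial measure name (one of {', '.join(MEASURE_NAMES)})")

    def collection(self, in_filter: bool) -> ast.CollectionNode:
        if in_filter:
            raise PblstlSemanticError(
                "entity collections are not allowed inside filter constraints"
            )
        if self.accept("regions"):
            return ast.EntityCollection("regions")
        if self.accept("clusters"):
            return ast.EntityCollection("clusters")
        if self.accept("filter"):
            self.expect("(")
            coll = self.collection(in_filter)
            self.expect(",")
            constraint = self.formula(in_filter=True)
            self.expect(")")
            return ast.Filter(coll, constraint)
        self.error("a collection (regions, clusters or filter(...))")


def parse_pblstl(text: str) -> list[ast.PblstlStatement]:
    """Parse specification text into a list of probabilistic statements."""
    parser = _Parser(_tokenize(text))
    return parser.specification()


def parse_pblstl_file(path) -> list[ast.PblstlStatement]:
    with open(path, encoding="utf-8") as fh:
        return parse_pblstl(fh.read())


def parse_formula(text: str) -> ast.FormulaNode:
    """Parse a bare (non-probabilistic) formula; convenience for tests/tools."""
    parser = _Parser(_tokenize(text))
    node = parser.formula()
    if parser.cur.kind != "eof":
        parser.error("end of input")
    return node
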