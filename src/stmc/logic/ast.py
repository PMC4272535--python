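"""AST node types for (probabilistic) bounded linear spatial temporal logic.

A specification is a list of probabilistic statements ``P ~ theta [ psi ]``
whose body ``psi`` mixes bounded temporal operators, Boolean connectives,
comparisons of numeric expressions, arithmetic over scalar state variables,
and statistical reducers over the dynamic collections of detected regions
and clusters (optionally narrowed by measure-constraint filters).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class FormulaNode:
    """Base class of Boolean-valued nodes."""


class NumericNode:
    """Base class of real-valued nodes."""


class CollectionNode:
    """Base class of entity-collection nodes."""


# --- Boolean layer ---------------------------------------------------------

@dataclass(frozen=True)
class Comparison(FormulaNode):
    left: NumericNode
    op: str  # one of < <= = >= >
    right: NumericNode


@dataclass(frozen=True)
class Not(FormulaNode):
    child: FormulaNode


@dataclass(frozen=True)
class BinaryBoolean(FormulaNode):
    op: str  # and | or | implies | equiv
    left: FormulaNode
    right: FormulaNode


# --- temporal layer --------------------------------------------------------

@dataclass(frozen=True)
class Future(FormulaNode):
    low: float
    high: float
    child: FormulaNode


@dataclass(frozen=True)
class Globally(FormulaNode):
    low: float
    high: float
    child: FormulaNode


@dataclass(frozen=True)
class Until(FormulaNode):
    low: float
    high: float
    left: FormulaNode
    right: FormulaNode


@dataclass(frozen=True)
class Next(FormulaNode):
    steps: int
    child: FormulaNode


# --- numeric layer ---------------------------------------------------------

@dataclass(frozen=True)
class Constant(NumericNode):
    value: float


@dataclass(frozen=True)
class StateVariable(NumericNode):
    """A numeric state variable reference ``{name}``."""

    name: str


@dataclass(frozen=True)
class MeasureRef(NumericNode):
    """A spatial-measure reference, valid only inside filter constraints."""

    name: str


@dataclass(frozen=True)
class Difference(NumericNode):
    """``d(expr)``: value at the next state minus value at the current one."""

    child: NumericNode


@dataclass(frozen=True)
class UnaryFunction(NumericNode):
    name: str
    child: NumericNode


@dataclass(frozen=True)
class BinaryFunction(NumericNode):
    name: str
    left: NumericNode
    right: NumericNode


@dataclass(frozen=True)
class Statistic(NumericNode):
    """A statistical reducer over an entity collection.

    ``count(collection)``; ``mean/median/mode/min/max/sum/stdev(collection,
    measure)``; ``percentile(collection, measure, q)``;
    ``covariance(collectionA, measureA, collectionB, measureB)``.
    """

    name: str
    collection: CollectionNode
    measure: str | None = None
    q: float | None = None
    collection2: CollectionNode | None = None
    measure2: str | None = None


# --- collections -----------------------------------------------------------

@dataclass(frozen=True)
class EntityCollection(CollectionNode):
    kind: str  # "regions" | "clusters"


@dataclass(frozen=True)
class Filter(CollectionNode):
    collection: CollectionNode
    constraint: FormulaNode  # Boolean tree over MeasureRef comparisons


# --- probabilistic wrapper -------------------------------------------------

@dataclass(frozen=True)
class PblstlStatement:
    """``P ~ theta [ psi ]`` with ``~`` in {<, <=, >, >=} and theta in (0, 1)."""

    comparator: str
    threshold: float
    formula: FormulaNode
    source: str = field(default="", compare=False)
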