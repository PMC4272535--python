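"""Bounded-semantics evaluator for spatial temporal logic over STML traces.

Temporal bounds are relative to the time value of the current evaluation
state and nest cumulatively; formulas over windows that extend past the end
of the trace raise :class:`~stmc.errors.TraceTooShortError`, so a trace
provider must supply traces covering the formula horizon.

Two situations yield a *missing value* rather than an error: a reference to
a numeric state variable absent from the current state, and a non-count
statistic over an empty collection.  Entity collections are dynamic sets
whose cardinality changes over time, so emptiness is a normal state: the
innermost enclosing comparison evaluates to false (and the event is logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError, TraceTooShortError
from ..stml import Experiment
from . import ast

logger = logging.getLogger(__name__)

EQUALITY_TOLERANCE = 1e-9


class _MissingValue(Exception):
    """Internal signal: makes the innermost enclosing comparison false."""


@dataclass
class TraceState:
    """One snapshot of a trace: time value, numeric variables, entities."""

    time: float
    numeric: dict[str, float] = field(default_factory=dict)
    regions: list = field(default_factory=list)
    clusters: list = field(default_factory=list)


@dataclass
class Trace:
    """A time-ordered sequence of states from one model execution."""

    states: list[TraceState]

    def __post_init__(self):
        if not self.states:
            raise ParameterError("a trace must contain at least one state")
        times = [s.time for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("trace time values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    @classmethod
    def from_experiment(cls, experiment: Experiment) -> "Trace":
        states = []
        for tp in experiment.timepoints:
            states.append(TraceState(
                time=float(tp.value),
                numeric=tp.numeric_values(),
                regions=[e for e in tp.spatialEntities if e.entityType == "region"],
                clusters=[e for e in tp.spatialEntities if e.entityType == "cluster"],
            ))
        return cls(states=states)


def _compare(left: float, right: float, op: str) -> bool:
    if op == "=":
        return abs(left - right) <= EQUALITY_TOLERANCE
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    raise ParameterError(f"unknown comparator {op!r}")


def _window_indices(trace: Trace, index: int, low: float, high: float) -> list[int]:
    t0 = trace.states[index].time
    if trace.states[-1].time - t0 < high:
        raise TraceTooShortError(
            f"temporal window [{low}, {high}] starting at time {t0} extends "
            f"beyond the trace end (last time {trace.states[-1].time})"
        )
    return [j for j in range(index, len(trace))
            if low <= trace.states[j].time - t0 <= high]


def evaluate_blstl(formula: ast.FormulaNode, trace: Trace, index: int = 0,
                   _memo: dict | None = None) -> bool:
    """Truth value of a formula on *trace* at state *index* (bounded semantics).

    Evaluation is pure, so results are memoised per (subformula, state)
    within one call; nested temporal windows revisit states heavily.
    """
    if _memo is None:
        _memo = {}
    key = (id(formula), index)
    if key in _memo:
        return _memo[key]
    result = _evaluate_blstl(formula, trace, index, _memo)
    _memo[key] = result
    return result


def _evaluate_blstl(formula: ast.FormulaNode, trace: Trace, index: int,
                    memo: dict) -> bool:
    if not (0 <= index < len(trace)):
        raise ParameterError(f"state index {index} outside trace of length {len(trace)}")

    def evaluate_blstl(f, t, i):  # shadow: recurse with the shared memo
        key = (id(f), i)
        if key in memo:
            return memo[key]
        result = _evaluate_blstl(f, t, i, memo)
        memo[key] = result
        return result

    if isinstance(formula, ast.Comparison):
        try:
            left = evaluate_numeric(formula.left, trace, index)
            right = evaluate_numeric(formula.right, trace, index)
        except _MissingValue as exc:
            logger.debug("comparison evaluates false: %s", exc)
            return False
        if math.isnan(left) or math.isnan(right):
            return False
        return _compare(left, right, formula.op)

    if isinstance(formula, ast.Not):
        return not evaluate_blstl(formula.child, trace, index)

    if isinstance(formula, ast.BinaryBoolean):
        left = evaluate_blstl(formula.left, trace, index)
        right = evaluate_blstl(formula.right, trace, index)
        if formula.op == "and":
            return left and right
        if formula.op == "or":
            return left or right
        if formula.op == "implies":
            return (not left) or right
        if formula.op == "equiv":
            return left == right
        raise ParameterError(f"unknown Boolean operator {formula.op!r}")

    if isinstance(formula, ast.Future):
        window = _window_indices(trace, index, formula.low, formula.high)
        return any(evaluate_blstl(formula.child, trace, j) for j in window)

    if isinstance(formula, ast.Globally):
        window = _window_indices(trace, index, formula.low, formula.high)
        return all(evaluate_blstl(formula.child, trace, j) for j in window)

    if isinstance(formula, ast.Until):
        window = _window_indices(trace, index, formula.low, formula.high)
        for j in window:
            if evaluate_blstl(formula.right, trace, j):
                if all(evaluate_blstl(formula.left, trace, k)
                       for k in range(index, j)):
                    return True
        return False

    if isinstance(formula, ast.Next):
        target = index + formula.steps
        if target >= len(trace):
            raise TraceTooShortError(
                f"X[{formula.steps}] at state {index} exceeds trace length {len(trace)}"
            )
        return evaluate_blstl(formula.child, trace, target)

    raise ParameterError(f"not a formula node: {formula!r}")


def _unary(name: str, x: float) -> float:
    if name == "abs":
        return abs(x)
    if name == "ceil":
        return float(math.ceil(x))
    if name == "floor":
        return float(math.floor(x))
    if name == "round":
        # round half away from zero
        return float(math.copysign(math.floor(abs(x) + 0.5), x))
    if name == "sign":
        return float(np.sign(x))
    if name == "sqrt":
        if x < 0:
            raise _MissingValue(f"sqrt of negative value {x}")
        return math.sqrt(x)
    if name == "trunc":
        return float(math.trunc(x))
    raise ParameterError(f"unknown unary function {name!r}")


def _binary(name: str, a: float, b: float) -> float:
    if name == "add":
        return a + b
    if name == "subtract":
        return a - b
    if name == "multiply":
        return a * b
    if name == "divide":
        if b == 0:
            raise _MissingValue("division by zero")
        return a / b
    if name == "power":
        try:
            result = a ** b
        except (OverflowError, ZeroDivisionError, ValueError) as exc:
            raise _MissingValue(f"power({a}, {b}) undefined") from exc
        if isinstance(result, complex):  # negative base, fractional exponent
            raise _MissingValue(f"power({a}, {b}) is complex-valued")
        return float(result)
    if name == "min":
        return min(a, b)
    if name == "max":
        return max(a, b)
    raise ParameterError(f"unknown binary function {name!r}")


def evaluate_numeric(expr: ast.NumericNode, trace: Trace, index: int) -> float:
    """Value of a numeric expression at state *index*."""
    if isinstance(expr, ast.Constant):
        return expr.value

    if isinstance(expr, ast.StateVariable):
        state = trace.states[index]
        if expr.name not in state.numeric:
            raise _MissingValue(
                f"numeric state variable {expr.name!r} missing at time "
                f"{state.time}"
            )
        return state.numeric[expr.name]

    if isinstance(expr, ast.MeasureRef):
        raise ParameterError(
            "spatial measure references are only valid inside filter constraints"
        )

    if isinstance(expr, ast.Difference):
        if index + 1 >= len(trace):
            raise TraceTooShortError(
                f"d(...) at the last state (index {index}) needs a successor state"
            )
        return (evaluate_numeric(expr.child, trace, index + 1)
                - evaluate_numeric(expr.child, trace, index))

    if isinstance(expr, ast.UnaryFunction):
        return _unary(expr.name, evaluate_numeric(expr.child, trace, index))

    if isinstance(expr, ast.BinaryFunction):
        return _binary(expr.name,
                       evaluate_numeric(expr.left, trace, index),
                       evaluate_numeric(expr.right, trace, index))

    if isinstance(expr, ast.Statistic):
        return apply_statistic(expr, trace, index)

    raise ParameterError(f"not a numeric node: {expr!r}")


def resolve_collection(node: ast.CollectionNode, trace: Trace, index: int) -> list:
    """The entity list a collection node denotes at state *index*."""
    state = trace.states[index]
    if isinstance(node, ast.EntityCollection):
        return list(state.regions if node.kind == "regions" else state.clusters)
    if isinstance(node, ast.Filter):
        return filter_entities(resolve_collection(node.collection, trace, index),
                               node.constraint)
    raise ParameterError(f"not a collection node: {node!r}")


def filter_entities(collection: list, constraint: ast.FormulaNode) -> list:
    """Subset of *collection* whose measures satisfy the constraint (order kept)."""
    return [e for e in collection if _constraint_holds(constraint, e)]


def _constraint_holds(node: ast.FormulaNode, entity) -> bool:
    if isinstance(node, ast.Comparison):
        return _compare(_measure_value(node.left, entity),
                        _measure_value(node.right, entity), node.op)
    if isinstance(node, ast.Not):
        return not _constraint_holds(node.child, entity)
    if isinstance(node, ast.BinaryBoolean):
        left = _constraint_holds(node.left, entity)
        right = _constraint_holds(node.right, entity)
        return {"and": left and right, "or": left or right,
                "implies": (not left) or right, "equiv": left == right}[node.op]
    raise ParameterError(f"invalid node inside filter constraint: {node!r}")


def _measure_value(node: ast.NumericNode, entity) -> float:
    if isinstance(node, ast.MeasureRef):
        return float(getattr(entity, node.name))
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.UnaryFunction):
        return _unary(node.name, _measure_value(node.child, entity))
    if isinstance(node, ast.BinaryFunction):
        return _binary(node.name, _measure_value(node.left, entity),
                       _measure_value(node.right, entity))
    raise ParameterError(f"invalid numeric node inside filter constraint: {node!r}")


def _measure_values(entities, measure: str) -> list[float]:
    return [float(getattr(e, measure)) for e in entities]


def apply_statistic(stat: ast.Statistic, trace: Trace, index: int) -> float:
    """Reduce an entity collection to a single real value."""
    entities = resolve_collection(stat.collection, trace, index)
    if stat.name == "count":
        return float(len(entities))

    if stat.name == "covariance":
        other = resolve_collection(stat.collection2, trace, index)
        n = min(len(entities), len(other))
        if len(entities) != len(other):
            logger.warning(
                "covariance collections differ in cardinality (%d vs %d); "
                "truncating to %d index-paired entities",
                len(entities), len(other), n,
            )
        if n < 2:
            raise _MissingValue("covariance needs at least two paired entities")
        a = np.array(_measure_values(entities[:n], stat.measure))
        b = np.array(_measure_values(other[:n], stat.measure2))
        return float(np.cov(a, b, ddof=1)[0, 1])

    if not entities:
        raise _MissingValue(
            f"{stat.name} over an empty collection at state index {index}"
        )
    values = _measure_values(entities, stat.measure)

    if stat.name == "percentile":
        # nearest-rank definition
        ordered = sorted(values)
        rank = max(1, math.ceil(stat.q / 100.0 * len(ordered)))
        return ordered[rank - 1]
    if stat.name == "mean":
        return float(np.mean(values))
    if stat.name == "median":
        return float(np.median(values))
    if stat.name == "min":
        return float(min(values))
    if stat.name == "max":
        return float(max(values))
    if stat.name == "sum":
        return float(sum(values))
    if stat.name == "stdev":
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    if stat.name == "mode":
        ordered = sorted(values)
        best, best_count = ordered[0], 0
        for v in ordered:
            c = sum(1 for w in ordered if w == v)
            if c > best_count:
                best, best_count = v, c
        return float(best)
    raise ParameterError(f"unknown statistic {stat.name!r}")
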