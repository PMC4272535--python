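"""Naive reference evaluator for the spatio-temporal logic, used as an oracle.

Implements the bounded semantics directly from the definitions by explicit
enumeration over states, deliberately sharing no code with the package's
evaluator (no memoisation, plain Python arithmetic, its own statistics).
Also provides seeded random generators for formulas and traces.
"""

from __future__ import annotations

import math
import random

from stmc.errors import TraceTooShortError
from stmc.logic import ast
from stmc.logic.evaluator import Trace, TraceState
from stmc.stml import MEASURE_NAMES, SpatialEntityRecord


class RefMissing(Exception):
    pass


def ref_eval(node, trace, index):
    if isinstance(node, ast.Comparison):
        try:
            lhs = ref_num(node.left, trace, index)
            rhs = ref_num(node.right, trace, index)
        except RefMissing:
            return False
        if math.isnan(lhs) or math.isnan(rhs):
            return False
        return ref_cmp(lhs, rhs, node.op)
    if isinstance(node, ast.Not):
        return not ref_eval(node.child, trace, index)
    if isinstance(node, ast.BinaryBoolean):
        a = ref_eval(node.left, trace, index)
        b = ref_eval(node.right, trace, index)
        if node.op == "and":
            return a and b
        if node.op == "or":
            return a or b
        if node.op == "implies":
            return (not a) or b
        return a == b
    if isinstance(node, (ast.Future, ast.Globally, ast.Until)):
        t0 = trace.states[index].time
        if trace.states[-1].time - t0 < node.high:
            raise TraceTooShortError("window exceeds trace")
        window = [j for j in range(index, len(trace.states))
                  if node.low <= trace.states[j].time - t0 <= node.high]
        if isinstance(node, ast.Future):
            return any(ref_eval(node.child, trace, j) for j in window)
        if isinstance(node, ast.Globally):
            return all(ref_eval(node.child, trace, j) for j in window)
        for j in window:
            if ref_eval(node.right, trace, j) and \
                    all(ref_eval(node.left, trace, k) for k in range(index, j)):
                return True
        return False
    if isinstance(node, ast.Next):
        if index + node.steps >= len(trace.states):
            raise TraceTooShortError("X exceeds trace")
        return ref_eval(node.child, trace, index + node.steps)
    raise AssertionError(node)


def ref_cmp(a, b, op):
    return {"=": abs(a - b) <= 1e-9, "<": a < b, "<=": a <= b,
            ">": a > b, ">=": a >= b}[op]


def ref_num(node, trace, index):
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.StateVariable):
        values = trace.states[index].numeric
        if node.name not in values:
            raise RefMissing(node.name)
        return values[node.name]
    if isinstance(node, ast.Difference):
        if index + 1 >= len(trace.states):
            raise TraceTooShortError("d at last state")
        return ref_num(node.child, trace, index + 1) - ref_num(node.child, trace, index)
    if isinstance(node, ast.UnaryFunction):
        x = ref_num(node.child, trace, index)
        if node.name == "abs":
            return abs(x)
        if node.name == "ceil":
            return math.ceil(x)
        if node.name == "floor":
            return math.floor(x)
        if node.name == "round":
            return math.copysign(math.floor(abs(x) + 0.5), x)
        if node.name == "sign":
            return (x > 0) - (x < 0)
        if node.name == "sqrt":
            if x < 0:
                raise RefMissing("sqrt")
            return math.sqrt(x)
        if node.name == "trunc":
            return math.trunc(x)
        raise AssertionError(node.name)
    if isinstance(node, ast.BinaryFunction):
        a = ref_num(node.left, trace, index)
        b = ref_num(node.right, trace, index)
        if node.name == "add":
            return a + b
        if node.name == "subtract":
            return a - b
        if node.name == "multiply":
            return a * b
        if node.name == "divide":
            if b == 0:
                raise RefMissing("divide by zero")
            return a / b
        if node.name == "power":
            try:
                result = a ** b
            except (OverflowError, ZeroDivisionError, ValueError) as exc:
                raise RefMissing("power") from exc
            if isinstance(result, complex):
                raise RefMissing("power complex")
            return float(result)
        if node.name == "min":
            return min(a, b)
        if node.name == "max":
            return max(a, b)
        raise AssertionError(node.name)
    if isinstance(node, ast.Statistic):
        return ref_stat(node, trace, index)
    raise AssertionError(node)


def ref_collection(node, trace, index):
    state = trace.states[index]
    if isinstance(node, ast.EntityCollection):
        return list(state.regions if node.kind == "regions" else state.clusters)
    entities = ref_collection(node.collection, trace, index)
    return [e for e in entities if ref_constraint(node.constraint, e)]


def ref_constraint(node, entity):
    if isinstance(node, ast.Comparison):
        return ref_cmp(ref_measure(node.left, entity),
                       ref_measure(node.right, entity), node.op)
    if isinstance(node, ast.Not):
        return not ref_constraint(node.child, entity)
    a = ref_constraint(node.left, entity)
    b = ref_constraint(node.right, entity)
    return {"and": a and b, "or": a or b,
            "implies": (not a) or b, "equiv": a == b}[node.op]


def ref_measure(node, entity):
    if isinstance(node, ast.MeasureRef):
        return getattr(entity, node.name)
    if isinstance(node, ast.Constant):
        return node.value
    raise AssertionError(node)


def ref_stat(node, trace, index):
    entities = ref_collection(node.collection, trace, index)
    if node.name == "count":
        return float(len(entities))
    if node.name == "covariance":
        other = ref_collection(node.collection2, trace, index)
        n = min(len(entities), len(other))
        if n < 2:
            raise RefMissing("covariance")
        xs = [getattr(e, node.measure) for e in entities[:n]]
        ys = [getattr(e, node.measure2) for e in other[:n]]
        mx = sum(xs) / n
        my = sum(ys) / n
        return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / (n - 1)
    if not entities:
        raise RefMissing(node.name)
    values = [float(getattr(e, node.measure)) for e in entities]
    if node.name == "percentile":
        ordered = sorted(values)
        rank = max(1, math.ceil(node.q / 100.0 * len(ordered)))
        return ordered[rank - 1]
    if node.name == "mean":
        return sum(values) / len(values)
    if node.name == "median":
        ordered = sorted(values)
        n = len(ordered)
        mid = n // 2
        return ordered[mid] if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2
    if node.name == "min":
        return min(values)
    if node.name == "max":
        return max(values)
    if node.name == "sum":
        return sum(values)
    if node.name == "stdev":
        n = len(values)
        if n < 2:
            return 0.0
        m = sum(values) / n
        return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    if node.name == "mode":
        ordered = sorted(values)
        return max(ordered, key=lambda v: (ordered.count(v), -v))
    raise AssertionError(node.name)


# --- seeded random instances -----------------------------------------------

_MEASURE_CHOICES = ("area", "perimeter", "density", "clusteredness",
                    "distanceFromOrigin", "circularMeasure")


def random_entity(rng: random.Random, kind: str) -> SpatialEntityRecord:
    values = {m: round(rng.uniform(0, 20), 2) for m in MEASURE_NAMES}
    values["angle"] = round(rng.uniform(0, 360), 2)
    for m in ("triangularMeasure", "rectangularMeasure", "circularMeasure"):
        values[m] = round(rng.random(), 3)
    return SpatialEntityRecord(entityType=kind, **values)


def random_trace(rng: random.Random, max_len: int = 10) -> Trace:
    length = rng.randint(2, max_len)
    states = []
    t = 0
    for _ in range(length):
        numeric = {}
        for name in ("A", "B"):
            if rng.random() < 0.85:  # sometimes missing
                numeric[name] = round(rng.uniform(-10, 10), 2)
        regions = [random_entity(rng, "region")
                   for _ in range(rng.randint(0, 3))]
        clusters = [random_entity(rng, "cluster")
                    for _ in range(rng.randint(0, 3))]
        states.append(TraceState(time=t, numeric=numeric,
                                 regions=regions, clusters=clusters))
        t += rng.randint(1, 2)
    return Trace(states=states)


def random_collection(rng: random.Random, depth: int) -> ast.CollectionNode:
    base = ast.EntityCollection(rng.choice(("regions", "clusters")))
    if depth > 0 and rng.random() < 0.4:
        constraint = ast.Comparison(
            ast.MeasureRef(rng.choice(_MEASURE_CHOICES)),
            rng.choice(("<", "<=", ">", ">=")),
            ast.Constant(round(rng.uniform(0, 15), 1)))
        if rng.random() < 0.3:
            constraint = ast.BinaryBoolean(
                rng.choice(("and", "or")), constraint,
                ast.Comparison(ast.MeasureRef(rng.choice(_MEASURE_CHOICES)),
                               ">", ast.Constant(round(rng.uniform(0, 15), 1))))
        return ast.Filter(base, constraint)
    return base


def random_numeric(rng: random.Random, depth: int) -> ast.NumericNode:
    if depth <= 0:
        choice = rng.random()
        if choice < 0.5:
            return ast.Constant(round(rng.uniform(-10, 10), 1))
        if choice < 0.8:
            return ast.StateVariable(rng.choice(("A", "B", "C")))
        return ast.Statistic("count", random_collection(rng, depth))
    choice = rng.random()
    if choice < 0.2:
        return ast.Difference(random_numeric(rng, depth - 1))
    if choice < 0.4:
        return ast.UnaryFunction(
            rng.choice(("abs", "ceil", "floor", "round", "sign", "sqrt", "trunc")),
            random_numeric(rng, depth - 1))
    if choice < 0.6:
        return ast.BinaryFunction(
            rng.choice(("add", "subtract", "multiply", "divide", "power",
                        "min", "max")),
            random_numeric(rng, depth - 1), random_numeric(rng, depth - 1))
    if choice < 0.85:
        name = rng.choice(("mean", "median", "mode", "min", "max", "sum",
                           "stdev"))
        return ast.Statistic(name, random_collection(rng, depth - 1),
                             measure=rng.choice(_MEASURE_CHOICES))
    if choice < 0.95:
        return ast.Statistic("percentile", random_collection(rng, depth - 1),
                             measure=rng.choice(_MEASURE_CHOICES),
                             q=rng.choice((0, 25, 50, 75, 100)))
    return ast.Statistic("covariance", random_collection(rng, depth - 1),
                         measure=rng.choice(_MEASURE_CHOICES),
                         collection2=random_collection(rng, depth - 1),
                         measure2=rng.choice(_MEASURE_CHOICES))


def random_formula(rng: random.Random, depth: int, horizon: int) -> ast.FormulaNode:
    if depth <= 0:
        return ast.Comparison(random_numeric(rng, 1),
                              rng.choice(("<", "<=", "=", ">=", ">")),
                              random_numeric(rng, 1))
    choice = rng.random()
    if choice < 0.3:
        return ast.Comparison(random_numeric(rng, depth),
                              rng.choice(("<", "<=", "=", ">=", ">")),
                              random_numeric(rng, depth))
    if choice < 0.4:
        return ast.Not(random_formula(rng, depth - 1, horizon))
    if choice < 0.6:
        return ast.BinaryBoolean(
            rng.choice(("and", "or", "implies", "equiv")),
            random_formula(rng, depth - 1, horizon),
            random_formula(rng, depth - 1, horizon))
    a = rng.randint(0, max(horizon // 2, 1))
    b = a + rng.randint(0, max(horizon - a, 1))
    if choice < 0.75:
        return ast.Future(a, b, random_formula(rng, depth - 1, horizon))
    if choice < 0.9:
        return ast.Globally(a, b, random_formula(rng, depth - 1, horizon))
    if choice < 0.97:
        return ast.Until(a, b, random_formula(rng, depth - 1, horizon),
                         random_formula(rng, depth - 1, horizon))
    return ast.Next(rng.randint(1, 3), random_formula(rng, depth - 1, horizon))
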