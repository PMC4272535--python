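"""Spatial Temporal Markup Language (STML) data model, reader, writer, validator.

STML records the output of spatio-temporal analysis as a time-ordered list of
timepoints.  Each timepoint holds the spatial entities (regions or clusters of
regions) detected at that instant -- each characterised by eleven spatial
measures -- together with named numeric state variables (e.g. concentrations,
cluster-validity indices).  Files are XML; the normative structure is the
companion schema ``schema/STML_L1V1.xsd`` shipped with the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from lxml import etree

from .errors import StmlParseError, StmlValidationError

SCHEMA_VERSION = "L1V1"

#: Spatial measure element names in serialisation order.
MEASURE_NAMES = (
    "clusteredness",
    "density",
    "area",
    "perimeter",
    "distanceFromOrigin",
    "angle",
    "triangularMeasure",
    "rectangularMeasure",
    "circularMeasure",
    "centroidX",
    "centroidY",
)

SHAPE_NAMES = ("triangular", "rectangular", "circular")
ENTITY_TYPES = ("region", "cluster")


@dataclass
class SpatialEntityRecord:
    """One detected region or cluster with its eleven spatial measures."""

    entityType: str
    clusteredness: float = 0.0
    density: float = 0.0
    area: float = 0.0
    perimeter: float = 0.0
    distanceFromOrigin: float = 0.0
    angle: float = 0.0
    triangularMeasure: float = 0.0
    rectangularMeasure: float = 0.0
    circularMeasure: float = 0.0
    centroidX: float = 0.0
    centroidY: float = 0.0
    shape: str | None = None

    def validate(self, where: str = "spatialEntity") -> None:
        if self.entityType not in ENTITY_TYPES:
            raise StmlValidationError(
                f"{where}/pseudo3D: type must be one of {ENTITY_TYPES}, "
                f"got {self.entityType!r}"
            )
        for name in ("clusteredness", "density", "area", "perimeter",
                     "distanceFromOrigin", "centroidX", "centroidY"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise StmlValidationError(
                    f"{where}/{name}: must be a finite non-negative real, got {v!r}"
                )
        if not (0.0 <= self.angle <= 360.0):
            raise StmlValidationError(
                f"{where}/angle: must lie in [0, 360], got {self.angle!r}"
            )
        for name in ("triangularMeasure", "rectangularMeasure", "circularMeasure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise StmlValidationError(
                    f"{where}/{name}: must lie in [0, 1], got {v!r}"
                )
        if self.shape is not None and self.shape not in SHAPE_NAMES:
            raise StmlValidationError(
                f"{where}/shape: must be one of {SHAPE_NAMES}, got {self.shape!r}"
            )


@dataclass
class NumericStateVariableRecord:
    """A named scalar state variable (e.g. a concentration) at one timepoint."""

    name: str
    value: float

    def validate(self, where: str = "numericStateVariable") -> None:
        if not self.name:
            raise StmlValidationError(f"{where}/name: must be a non-empty string")
        if not math.isfinite(self.value):
            raise StmlValidationError(
                f"{where}/value: must be a finite real, got {self.value!r}"
            )


@dataclass
class Timepoint:
    """One recorded instant: spatial entities plus numeric state variables.

    ``value`` is the non-negative integer time index; it may be left unset
    (``None``) and later filled in by :func:`resolve_timepoint_values`.
    """

    value: int | None = None
    spatialEntities: list[SpatialEntityRecord] = field(default_factory=list)
    numericStateVariables: list[NumericStateVariableRecord] = field(default_factory=list)

    def validate(self, where: str = "timepoint") -> None:
        if self.value is not None and (not isinstance(self.value, (int, np.integer))
                                       or self.value < 0):
            raise StmlValidationError(
                f"{where}@value: must be a non-negative integer, got {self.value!r}"
            )
        for i, ent in enumerate(self.spatialEntities):
            ent.validate(f"{where}/spatialEntity[{i}]")
        names = [v.name for v in self.numericStateVariables]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise StmlValidationError(
                f"{where}/numericStateVariable: duplicate names {sorted(dup)}"
            )
        for i, var in enumerate(self.numericStateVariables):
            var.validate(f"{where}/numericStateVariable[{i}]")

    def numeric_values(self) -> dict[str, float]:
        return {v.name: v.value for v in self.numericStateVariables}


@dataclass
class Experiment:
    """A complete STML time series: a non-empty ordered list of timepoints."""

    timepoints: list[Timepoint] = field(default_factory=list)

    def validate(self, resolved: bool = True) -> None:
        if not self.timepoints:
            raise StmlValidationError(
                "experiment: must contain at least one timepoint"
            )
        for i, tp in enumerate(self.timepoints):
            tp.validate(f"experiment/timepoint[{i}]")
        if resolved:
            values = [tp.value for tp in self.timepoints]
            if any(v is None for v in values):
                raise StmlValidationError(
                    "experiment: timepoint values must be resolved "
                    "(use resolve_timepoint_values)"
                )
            for i in range(1, len(values)):
                if values[i] <= values[i - 1]:
                    raise StmlValidationError(
                        f"experiment/timepoint[{i}]@value: values must be strictly "
                        f"increasing, got {values[i - 1]} then {values[i]}"
                    )


def resolve_timepoint_values(experiment: Experiment) -> Experiment:
    """Fill in missing timepoint values.

    ``t_i`` is the predefined value when one was given; ``0`` for the first
    timepoint otherwise; and the previous resolved value plus one otherwise.
    Returns a new :class:`Experiment`; raises if resolution yields a
    non-increasing sequence.  Idempotent.
    """
    resolved: list[Timepoint] = []
    prev: int | None = None
    for i, tp in enumerate(experiment.timepoints):
        if tp.value is not None:
            value = int(tp.value)
        elif i == 0:
            value = 0
        else:
            value = prev + 1
        if prev is not None and value <= prev:
            raise StmlValidationError(
                f"experiment/timepoint[{i}]@value: resolved value {value} is not "
                f"greater than the previous value {prev}"
            )
        resolved.append(replace(tp, value=value))
        prev = value
    out = Experiment(timepoints=resolved)
    return out


def _schema_path() -> Path:
    return Path(str(resources.files("stmc").joinpath("schema/STML_L1V1.xsd")))


def load_schema() -> etree.XMLSchema:
    """Load the shipped normative XSD schema."""
    with open(_schema_path(), "rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def validate_against_schema(path) -> None:
    """Raise :class:`StmlValidationError` unless *path* validates against the XSD."""
    schema = load_schema()
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise StmlParseError(f"{path}: not well-formed XML: {exc}") from exc
    if not schema.validate(doc):
        raise StmlValidationError(f"{path}: schema violation: {schema.error_log}")


def _parse_float(elem, where: str) -> float:
    text = (elem.text or "").strip()
    try:
        return float(text)
    except ValueError as exc:
        raise StmlValidationError(f"{where}: not a number: {text!r}") from exc


def read_stml(path) -> Experiment:
    """Read and validate an STML file, resolving timepoint values.

    Raises :class:`StmlParseError` on malformed XML and
    :class:`StmlValidationError` on constraint violations; the error message
    names the offending element and constraint.
    """
    try:
        doc = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise StmlParseError(f"{path}: {exc}") from exc
    root = doc.getroot()
    if root.tag != "experiment":
        raise StmlValidationError(
            f"{path}: root element must be <experiment>, got <{root.tag}>"
        )
    version = root.get("stmlVersion", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        warnings.warn(
            f"{path}: declared STML version {version!r}; validating against "
            f"{SCHEMA_VERSION} only",
            stacklevel=2,
        )

    timepoints: list[Timepoint] = []
    for ti, tp_elem in enumerate(root.findall("timepoint")):
        where = f"experiment/timepoint[{ti}]"
        raw_value = tp_elem.get("value")
        if raw_value is not None:
            try:
                value = int(raw_value)
            except ValueError as exc:
                raise StmlValidationError(
                    f"{where}@value: must be a non-negative integer, got {raw_value!r}"
                ) from exc
            if value < 0:
                raise StmlValidationError(
                    f"{where}@value: must be a non-negative integer, got {value}"
                )
        else:
            value = None

        entities: list[SpatialEntityRecord] = []
        for si, se_elem in enumerate(tp_elem.findall("spatialEntity")):
            p3d = se_elem.find("pseudo3D")
            if p3d is None:
                raise StmlValidationError(
                    f"{where}/spatialEntity[{si}]: missing <pseudo3D> child"
                )
            etype = p3d.get("type")
            kwargs = {}
            for m in MEASURE_NAMES:
                child = p3d.find(m)
                if child is None:
                    raise StmlValidationError(
                        f"{where}/spatialEntity[{si}]/pseudo3D: missing <{m}>"
                    )
                kwargs[m] = _parse_float(child, f"{where}/spatialEntity[{si}]/{m}")
            shape_elem = p3d.find("shape")
            shape = shape_elem.text.strip() if shape_elem is not None else None
            entities.append(SpatialEntityRecord(entityType=etype, shape=shape, **kwargs))

        variables: list[NumericStateVariableRecord] = []
        for vi, var_elem in enumerate(tp_elem.findall("numericStateVariable")):
            vwhere = f"{where}/numericStateVariable[{vi}]"
            name_elem = var_elem.find("name")
            value_elem = var_elem.find("value")
            if name_elem is None or value_elem is None:
                raise StmlValidationError(
                    f"{vwhere}: must contain <name> and <value> children"
                )
            variables.append(NumericStateVariableRecord(
                name=(name_elem.text or "").strip(),
                value=_parse_float(value_elem, f"{vwhere}/value"),
            ))

        timepoints.append(Timepoint(value=value, spatialEntities=entities,
                                    numericStateVariables=variables))

    experiment = Experiment(timepoints=timepoints)
    if not experiment.timepoints:
        raise StmlValidationError(
            f"{path}: experiment must contain at least one timepoint"
        )
    experiment = resolve_timepoint_values(experiment)
    experiment.validate(resolved=True)
    return experiment


def _fmt(value: float) -> str:
    # xs:decimal forbids exponent notation; shortest positional repr round-trips.
    return np.format_float_positional(float(value), trim="-")


def write_stml(experiment: Experiment, path) -> None:
    """Serialise a valid :class:`Experiment` to an STML XML file.

    Timepoint values must already be resolved; invariant violations refuse
    to write.  Element ordering is deterministic (the schema order).
    """
    experiment.validate(resolved=True)
    root = etree.Element("experiment", stmlVersion=SCHEMA_VERSION)
    for tp in experiment.timepoints:
        tp_elem = etree.SubElement(root, "timepoint", value=str(int(tp.value)))
        for ent in tp.spatialEntities:
            se = etree.SubElement(tp_elem, "spatialEntity")
            p3d = etree.SubElement(se, "pseudo3D", type=ent.entityType)
            for m in MEASURE_NAMES:
                etree.SubElement(p3d, m).text = _fmt(getattr(ent, m))
            if ent.shape is not None:
                etree.SubElement(p3d, "shape").text = ent.shape
        for var in tp.numericStateVariables:
            v = etree.SubElement(tp_elem, "numericStateVariable")
            etree.SubElement(v, "name").text = var.name
            etree.SubElement(v, "value").text = _fmt(var.value)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
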