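"""Tabular data model: variable specs, cohort schema, and CSV round-trip.

A :class:`CohortSchema` declares an ordered list of predictors, each either
*discrete* (a finite set of integer codes, e.g. 0/1 indicator variables) or
*continuous* (any value within an interval), plus a binary outcome column.
A :class:`Cohort` binds an ``(n, p)`` value matrix and ``n`` class labels to
such a schema and is the unit every other module operates on.

The split of predictors into the discrete set ``D`` and continuous set ``C``
drives the whole rule-extraction pipeline: trees test discrete attributes with
``=`` and continuous ones with ``<=``/``>``, and the recursion consumes
discrete attributes one antecedent at a time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

DISCRETE = "discrete"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class VariableSpec:
    """One predictor: name, kind, and permitted domain.

    Parameters
    ----------
    name
        Identifier matching ``[A-Za-z][A-Za-z0-9_]*``.
    kind
        ``"discrete"`` or ``"continuous"``.
    domain
        For discrete variables, a tuple of >=2 permitted integer codes.
        For continuous variables, an ``(low, high)`` interval where either
        bound may be ``None`` (open).
    units
        Free-text annotation (e.g. ``"g"``, ``"years"``).
    """

    name: str
    kind: str
    domain: tuple = ()
    units: str = ""

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise SchemaError(f"invalid variable name {self.name!r}")
        if self.kind not in (DISCRETE, CONTINUOUS):
            raise SchemaError(f"{self.name}: kind must be discrete or continuous, got {self.kind!r}")
        if self.kind == DISCRETE:
            codes = tuple(self.domain)
            if len(codes) < 2 or len(set(codes)) != len(codes):
                raise SchemaError(f"{self.name}: discrete domain needs >=2 distinct codes")
            if any(int(c) != c for c in codes):
                raise SchemaError(f"{self.name}: discrete codes must be integers")
            object.__setattr__(self, "domain", tuple(int(c) for c in codes))
        else:
            if len(self.domain) != 2:
                raise SchemaError(f"{self.name}: continuous domain must be (low, high)")
            lo, hi = self.domain
            if lo is not None and hi is not None and not lo < hi:
                raise SchemaError(f"{self.name}: continuous lower bound must be < upper bound")
            object.__setattr__(
                self,
                "domain",
                (None if lo is None else float(lo), None if hi is None else float(hi)),
            )

    def contains(self, value: float) -> bool:
        """True if *value* lies in this variable's declared domain."""
        if self.kind == DISCRETE:
            return float(value) == int(value) and int(value) in self.domain
        if not np.isfinite(value):
            return False
        lo, hi = self.domain
        if lo is not None and value < lo:
            return False
        if hi is not None and value > hi:
            return False
        return True


@dataclass(frozen=True)
class CohortSchema:
    """Ordered predictor list plus the binary outcome declaration."""

    variables: tuple
    outcome_name: str
    positive_label: int
    negative_label: int
    name: str = "unnamed"

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if not names:
            raise SchemaError("schema needs at least one predictor")
        if self.outcome_name in names:
            raise SchemaError(f"outcome {self.outcome_name!r} clashes with a predictor name")
        if not _NAME_RE.match(self.outcome_name):
            raise SchemaError(f"invalid outcome name {self.outcome_name!r}")
        if self.positive_label == self.negative_label:
            raise SchemaError("positive and negative labels must differ")

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    @property
    def p(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def variable(self, name: str) -> VariableSpec:
        return self.variables[self.index(name)]

    @property
    def discrete_names(self) -> list:
        return [v.name for v in self.variables if v.kind == DISCRETE]

    @property
    def continuous_names(self) -> list:
        return [v.name for v in self.variables if v.kind == CONTINUOUS]

    def subset(self, names) -> "CohortSchema":
        """Schema restricted to the given predictors (schema order preserved)."""
        keep = set(names)
        vs = [v for v in self.variables if v.name in keep]
        missing = keep - {v.name for v in vs}
        if missing:
            raise SchemaError(f"unknown variables {sorted(missing)}")
        return CohortSchema(tuple(vs), self.outcome_name, self.positive_label,
                            self.negative_label, name=self.name)


def split_attributes(schema: CohortSchema):
    """Partition the schema's predictors into (discrete D, continuous C).

    Order follows the schema; the two lists are disjoint and jointly cover
    every predictor.
    """
    return schema.discrete_names, schema.continuous_names


@dataclass
class Cohort:
    """An ``(n, p)`` sample matrix and labels bound to a schema.

    ``X`` is float64 (discrete codes stored as whole floats); ``y`` holds the
    schema's two class codes.
    """

    schema: CohortSchema
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != self.schema.p:
            raise CohortValidationError(
                f"X must be (n, {self.schema.p}), got {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise CohortValidationError("labels length must match row count")
        if self.n < 1:
            raise CohortValidationError("cohort needs at least one row")
        self.validate()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def validate(self):
        """Check every cell against its VariableSpec; raise on first group of violations."""
        bad = []
        for j, var in enumerate(self.schema.variables):
            col = self.X[:, j]
            if var.kind == DISCRETE:
                ok = np.isin(col, np.asarray(var.domain, dtype=float)) & (col == np.round(col))
            else:
                ok = np.isfinite(col)
                lo, hi = var.domain
                if lo is not None:
                    ok &= col >= lo
                if hi is not None:
                    ok &= col <= hi
            for i in np.flatnonzero(~ok)[:5]:
                bad.append(f"row {i}, column {var.name!r}: value {col[i]!r} outside domain")
        labels_ok = np.isin(self.y, [self.schema.positive_label, self.schema.negative_label])
        for i in np.flatnonzero(~labels_ok)[:5]:
            bad.append(f"row {i}, outcome: label {self.y[i]!r} is not a declared class code")
        if bad:
            raise CohortValidationError("; ".join(bad))

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.schema.index(name)]

    def take(self, idx) -> "Cohort":
        """Row subset (boolean mask or index array)."""
        return Cohort(self.schema, self.X[idx], self.y[idx])

    def project(self, names) -> "Cohort":
        """Column subset onto ``schema.subset(names)``."""
        sub = self.schema.subset(names)
        cols = [self.schema.index(v.name) for v in sub.variables]
        return Cohort(sub, self.X[:, cols], self.y)

    def class_counts(self):
        """(n_positive, n_negative)."""
        pos = int(np.sum(self.y == self.schema.positive_label))
        return pos, self.n - pos


def read_cohort(path, schema: CohortSchema) -> Cohort:
    """Read a CSV cohort, validating every cell against the schema.

    The file may list columns in any order; extra columns are ignored with a
    warning. Missing columns, empty cells, non-numeric cells and
    out-of-domain discrete codes are hard errors with row/column coordinates
    (values are never imputed).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    wanted = schema.names + [schema.outcome_name]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in wanted]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, extra)
    if len(df) == 0:
        raise CohortValidationError(f"{path}: no data rows")

    values = np.empty((len(df), schema.p), dtype=float)
    for j, name in enumerate(schema.names):
        values[:, j] = _parse_numeric(df[name], name)
    y = _parse_numeric(df[schema.outcome_name], schema.outcome_name)
    if not np.all(y == np.round(y)):
        i = int(np.flatnonzero(y != np.round(y))[0])
        raise CohortValidationError(
            f"row {i}, column {schema.outcome_name!r}: class code must be an integer")
    return Cohort(schema, values, y.astype(int))


def _parse_numeric(series: pd.Series, name: str) -> np.ndarray:
    raw = series.str.strip()
    empty = raw == ""
    if empty.any():
        i = int(np.flatnonzero(empty.to_numpy())[0])
        raise CohortValidationError(f"row {i}, column {name!r}: empty cell")
    # float() is correctly rounded (pandas' fast parser can be an ulp off,
    # which would break the bit-exact round-trip contract)
    values = np.empty(len(raw))
    for i, s in enumerate(raw.to_numpy()):
        try:
            values[i] = float(s)
        except ValueError:
            raise CohortValidationError(
                f"row {i}, column {name!r}: non-numeric value {s!r}") from None
    return values


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort as CSV (header = schema order then outcome).

    Continuous values are printed with ``repr`` (17 significant digits) so
    ``read_cohort(write_cohort(x))`` reproduces ``x`` bit-exactly; discrete
    codes and labels are printed as integers.
    """
    path = Path(path)
    sch = cohort.schema
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(",".join(sch.names + [sch.outcome_name]) + "\n")
            kinds = [v.kind for v in sch.variables]
            for i in range(cohort.n):
                cells = [
                    str(int(v)) if k == DISCRETE else repr(float(v))
                    for k, v in zip(kinds, cohort.X[i])
                ]
                cells.append(str(int(cohort.y[i])))
                fh.write(",".join(cells) + "\n")
    except OSError as exc:
        raise SchemaError(f"cannot write cohort to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# schema (de)serialization

def schema_from_dict(doc: dict) -> CohortSchema:
    try:
        variables = []
        for entry in doc["variables"]:
            kind = entry["kind"]
            if kind == DISCRETE:
                domain = tuple(entry["domain"])
            else:
                dom = entry.get("domain", [None, None])
                domain = (dom[0], dom[1])
            variables.append(VariableSpec(entry["name"], kind, domain, entry.get("units", "")))
        outcome = doc["outcome"]
        return CohortSchema(
            tuple(variables),
            outcome_name=outcome["name"],
            positive_label=int(outcome["positive_label"]),
            negative_label=int(outcome["negative_label"]),
            name=doc.get("name", "unnamed"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema document: {exc}") from exc


def schema_to_dict(schema: CohortSchema) -> dict:
    return {
        "name": schema.name,
        "variables": [
            {"name": v.name, "kind": v.kind, "domain": list(v.domain), "units": v.units}
            for v in schema.variables
        ],
        "outcome": {
            "name": schema.outcome_name,
            "positive_label": schema.positive_label,
            "negative_label": schema.negative_label,
        },
    }


def load_schema(path) -> CohortSchema:
    """Load a schema from a YAML (or JSON) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return schema_from_dict(doc)


def perinatal_schema() -> CohortSchema:
    """The packaged 52-variable perinatal schema.

    Predictors cover maternal characteristics, maternal/family history,
    obstetric history and pregnancy complications for singleton deliveries
    after 36 weeks; the outcome distinguishes emergency cesarean section
    (class 1, positive) from vaginal delivery or elective cesarean (class 2).

    Count-valued history variables (parity, gravida, prior cesareans, prior
    preterm births, spontaneous abortions) are declared *continuous* so that
    threshold conditions such as ``prior_cs > 0.32`` type-check; published
    rule sets in this domain threshold these counts at fractional values,
    which suggests they were scaled before training and makes an integer
    declaration unusable.
    """
    ref = _importlib_resources.files("rerx.resources") / "perinatal_schema.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return schema_from_dict(yaml.safe_load(fh))
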