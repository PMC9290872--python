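"""Rule data model, plain-text DSL, application engine and auditor.

A :class:`Rule` is an ordered conjunction of conditions with a class
consequent, in the classic if–then form used for interpretable clinical
classifiers::

    IF birth_weight <= 2456 AND prior_cs > 0.32 THEN 1

Conditions on discrete attributes use ``=``; conditions on continuous
attributes use ``<=`` / ``>`` (closed/open boundary). A rule emitted by the
hyperplane fallback carries a single linear condition over continuous
attributes, rendered as ``IF 0.5*a + -1.2*b <= 3.0 THEN 2``.

A :class:`RuleSet` is an *ordered* list of rules with a default class:
classification is first-match-wins, which makes the listed order operative
when antecedents overlap (published rule tables occasionally contain
contradictory duplicate antecedents; the auditor reports such conflicts
instead of resolving them silently).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources as _importlib_resources
from pathlib import Path

import numpy as np

from .errors import RuleParseError, SchemaError
from .schema import CONTINUOUS, DISCRETE, Cohort, CohortSchema

LE, GT, EQ = "<=", ">", "="

ORIGIN_TREE = "tree"
ORIGIN_HYPERPLANE = "hyperplane"
ORIGIN_MANUAL = "manual"


@dataclass(frozen=True)
class Condition:
    """Atomic test ``attribute op value``.

    ``=`` is only valid on discrete attributes; ``<=``/``>`` only on
    continuous ones (checked against the schema at rule validation).
    """

    attribute: str
    op: str
    value: float

    def __post_init__(self):
        if self.op not in (LE, GT, EQ):
            raise RuleParseError(f"unknown operator {self.op!r}")
        object.__setattr__(self, "value", float(self.value))

    def holds(self, x: float) -> bool:
        if self.op == LE:
            return x <= self.value
        if self.op == GT:
            return x > self.value
        return x == self.value

    def render(self) -> str:
        v = int(self.value) if self.op == EQ else _fmt(self.value)
        return f"{self.attribute} {self.op} {v}"


@dataclass(frozen=True)
class LinearCondition:
    """Half-space test ``sum_i coef_i * attr_i (<=|>) threshold``."""

    attributes: tuple
    coefficients: tuple
    op: str
    threshold: float

    def __post_init__(self):
        if self.op not in (LE, GT):
            raise RuleParseError("linear conditions use <= or > only")
        if len(self.attributes) != len(self.coefficients) or not self.attributes:
            raise RuleParseError("linear condition needs matching attributes/coefficients")
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "threshold", float(self.threshold))

    def render(self) -> str:
        terms = " + ".join(f"{_fmt(c)}*{a}" for a, c in zip(self.attributes, self.coefficients))
        return f"{terms} {self.op} {_fmt(self.threshold)}"


def _fmt(x: float) -> str:
    """Shortest decimal that round-trips through float()."""
    return repr(float(x))


@dataclass(frozen=True)
class Rule:
    """Conjunctive rule: ordered conditions, class consequent, statistics."""

    conditions: tuple
    consequent: int
    support: float = None
    error: float = None
    origin: str = ORIGIN_TREE

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def validate(self, schema: CohortSchema):
        for cond in self.conditions:
            if isinstance(cond, LinearCondition):
                for a in cond.attributes:
                    if schema.variable(a).kind != CONTINUOUS:
                        raise SchemaError(f"linear condition on non-continuous attribute {a!r}")
            else:
                kind = schema.variable(cond.attribute).kind
                if cond.op == EQ and kind != DISCRETE:
                    raise SchemaError(f"'=' condition on continuous attribute {cond.attribute!r}")
                if cond.op in (LE, GT) and kind != CONTINUOUS:
                    raise SchemaError(f"{cond.op!r} condition on discrete attribute {cond.attribute!r}")
        if self.consequent not in (schema.positive_label, schema.negative_label):
            raise SchemaError(f"rule consequent {self.consequent} is not a declared class code")

    def matches_row(self, row: np.ndarray, schema: CohortSchema) -> bool:
        return bool(self.matches(row[np.newaxis, :], schema)[0])

    def matches(self, X: np.ndarray, schema: CohortSchema) -> np.ndarray:
        """Vectorized antecedent match over an (n, p) matrix."""
        out = np.ones(X.shape[0], dtype=bool)
        for cond in self.conditions:
            if isinstance(cond, LinearCondition):
                z = np.zeros(X.shape[0])
                for a, c in zip(cond.attributes, cond.coefficients):
                    z += c * X[:, schema.index(a)]
                out &= (z <= cond.threshold) if cond.op == LE else (z > cond.threshold)
            else:
                col = X[:, schema.index(cond.attribute)]
                if cond.op == LE:
                    out &= col <= cond.value
                elif cond.op == GT:
                    out &= col > cond.value
                else:
                    out &= col == cond.value
        return out


@dataclass
class RuleSet:
    """Ordered rules + default class; first match wins."""

    rules: list
    default_class: int
    schema_name: str = "unnamed"

    def __post_init__(self):
        if not self.rules:
            raise SchemaError("a rule set must contain at least one rule")

    def __len__(self):
        return len(self.rules)

    def validate(self, schema: CohortSchema):
        for r in self.rules:
            r.validate(schema)
        if self.default_class not in (schema.positive_label, schema.negative_label):
            raise SchemaError("default class is not a declared class code")


# ---------------------------------------------------------------------------
# interval merging

def merge_conditions(conditions) -> tuple:
    """Canonicalize a conjunction: per continuous attribute keep the tightest
    ``<=`` (minimum) and ``>`` (maximum); per discrete attribute one ``=``
    (contradictory codes are kept verbatim — the region is then empty and the
    auditor flags it). Linear conditions are kept as-is, deduplicated.
    Condition order follows first appearance.
    """
    upper, lower, eq_codes = {}, {}, {}
    order, linear = [], []
    for cond in conditions:
        if isinstance(cond, LinearCondition):
            if cond not in linear:
                linear.append(cond)
                order.append(("lin", len(linear) - 1))
            continue
        a = cond.attribute
        if cond.op == LE:
            if a not in upper:
                order.append((LE, a))
            upper[a] = min(upper.get(a, np.inf), cond.value)
        elif cond.op == GT:
            if a not in lower:
                order.append((GT, a))
            lower[a] = max(lower.get(a, -np.inf), cond.value)
        else:
            if a not in eq_codes:
                order.append((EQ, a))
                eq_codes[a] = cond.value
            elif eq_codes[a] != cond.value:
                eq_codes[a] = (eq_codes[a], cond.value)  # contradictory: empty region
    out = []
    for tag, key in order:
        if tag == "lin":
            out.append(linear[key])
        elif tag == LE:
            out.append(Condition(key, LE, upper[key]))
        elif tag == GT:
            out.append(Condition(key, GT, lower[key]))
        else:
            codes = eq_codes[key]
            if isinstance(codes, tuple):
                out.extend(Condition(key, EQ, c) for c in codes)
            else:
                out.append(Condition(key, EQ, codes))
    return tuple(out)


def _region(rule: Rule):
    """Canonical region: ({attr: (lo, hi)}, {attr: code or None-if-contradictory},
    frozenset of linear conditions). ``None`` marks an empty region."""
    upper, lower, eq_codes, linear = {}, {}, {}, set()
    for cond in rule.conditions:
        if isinstance(cond, LinearCondition):
            linear.add(cond)
            continue
        a = cond.attribute
        if cond.op == LE:
            upper[a] = min(upper.get(a, np.inf), cond.value)
        elif cond.op == GT:
            lower[a] = max(lower.get(a, -np.inf), cond.value)
        else:
            if a in eq_codes and eq_codes[a] != cond.value:
                return None
            eq_codes[a] = cond.value
    intervals = {}
    for a in set(upper) | set(lower):
        lo, hi = lower.get(a, -np.inf), upper.get(a, np.inf)
        if lo >= hi:
            return None
        intervals[a] = (lo, hi)
    return intervals, eq_codes, frozenset(linear)


def _implies(inner, outer) -> bool:
    """True if region *inner* is contained in region *outer* (syntactic check:
    sufficient, not complete — linear conditions must match exactly)."""
    if inner is None:
        return True
    if outer is None:
        return False
    iv_i, eq_i, lin_i = inner
    iv_o, eq_o, lin_o = outer
    for a, (lo_o, hi_o) in iv_o.items():
        if a not in iv_i:
            return False
        lo_i, hi_i = iv_i[a]
        if lo_i < lo_o or hi_i > hi_o:
            return False
    for a, code in eq_o.items():
        if eq_i.get(a) != code:
            return False
    return lin_o <= lin_i


# ---------------------------------------------------------------------------
# application engine

def apply_ruleset(ruleset: RuleSet, sample, schema: CohortSchema):
    """Classify one sample: (class code, fired rule index; -1 = default)."""
    row = np.asarray(sample, dtype=float)
    for i, rule in enumerate(ruleset.rules):
        if rule.matches_row(row, schema):
            return rule.consequent, i
    return ruleset.default_class, -1


def apply_ruleset_cohort(ruleset: RuleSet, cohort: Cohort):
    """Vectorized first-match classification of a whole cohort.

    Returns (predicted classes, fired rule indices), index -1 for default.
    """
    n = cohort.n
    fired = np.full(n, -1, dtype=int)
    pred = np.full(n, ruleset.default_class, dtype=int)
    undecided = np.ones(n, dtype=bool)
    for i, rule in enumerate(ruleset.rules):
        if not undecided.any():
            break
        m = rule.matches(cohort.X, cohort.schema) & undecided
        pred[m] = rule.consequent
        fired[m] = i
        undecided &= ~m
    return pred, fired


def rule_support_error(rule: Rule, cohort: Cohort):
    """(support, error) of a rule on a cohort.

    support = matching rows / n; error = matching rows whose label differs
    from the consequent / matching rows (0 by convention when nothing
    matches).
    """
    m = rule.matches(cohort.X, cohort.schema)
    nm = int(m.sum())
    support = nm / cohort.n
    error = 0.0 if nm == 0 else float(np.sum(cohort.y[m] != rule.consequent)) / nm
    return support, error


def annotate_ruleset(ruleset: RuleSet, cohort: Cohort) -> RuleSet:
    """Return a copy whose rules carry support/error computed on *cohort*."""
    new = [replace(r, support=rule_support_error(r, cohort)[0],
                   error=rule_support_error(r, cohort)[1]) for r in ruleset.rules]
    return RuleSet(new, ruleset.default_class, ruleset.schema_name)


# ---------------------------------------------------------------------------
# auditor

def audit_ruleset(ruleset: RuleSet, cohort: Cohort = None) -> dict:
    """Static (and optionally empirical) health report for a rule set.

    Reports per-rule condition counts, antecedent-identical pairs with
    differing consequents (*conflicts*), rules shadowed by an earlier rule
    whose region contains theirs (*unreachable*), rules whose merged region
    is empty (*infeasible*), and — when a cohort is supplied — per-rule
    support and error on it.

    Unreachability by a *union* of earlier rules (no single one containing
    the later region) is not detected; the check is deliberately syntactic
    and sound rather than complete.
    """
    regions = [_region(r) for r in ruleset.rules]
    conflicts, unreachable, infeasible = [], [], []
    for j, rj in enumerate(regions):
        if rj is None:
            infeasible.append(j)
        for i in range(j):
            ri = regions[i]
            if ri is not None and rj is not None and ri == rj:
                if ruleset.rules[i].consequent != ruleset.rules[j].consequent:
                    conflicts.append((i, j))
            if _implies(rj, ri):
                if j not in unreachable:
                    unreachable.append(j)
    report = {
        "n_rules": len(ruleset.rules),
        "condition_counts": [r.n_conditions for r in ruleset.rules],
        "conflicts": conflicts,
        "n_conflicts": len(conflicts),
        "unreachable": unreachable,
        "infeasible": infeasible,
        "default_class": ruleset.default_class,
    }
    if cohort is not None:
        se = [rule_support_error(r, cohort) for r in ruleset.rules]
        report["support"] = [s for s, _ in se]
        report["error"] = [e for _, e in se]
    return report


# ---------------------------------------------------------------------------
# DSL parser / renderer

_LINEAR_TERM_RE = re.compile(r"^\s*([^\s*]+)\s*\*\s*([A-Za-z][A-Za-z0-9_]*)\s*$")


def parse_ruleset(path, schema: CohortSchema) -> RuleSet:
    """Parse a rule DSL file and validate it against *schema*.

    Grammar (one statement per line; ``#`` starts a comment)::

        IF <cond> AND <cond> ... THEN <class>
        IF TRUE THEN <class>
        DEFAULT <class>
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return parse_ruleset_text(text, schema, source=str(path))


def parse_ruleset_text(text: str, schema: CohortSchema, source: str = "<string>") -> RuleSet:
    rules = []
    default = schema.negative_label
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            if line.upper().startswith("DEFAULT"):
                default = int(line.split(None, 1)[1])
                continue
            rules.append(_parse_rule_line(line, schema))
        except (RuleParseError, SchemaError) as exc:
            raise RuleParseError(f"{source}:{lineno}: {exc}") from None
        except (IndexError, ValueError) as exc:
            raise RuleParseError(f"{source}:{lineno}: malformed line {line!r} ({exc})") from None
    rs = RuleSet(rules, default_class=default, schema_name=schema.name)
    try:
        rs.validate(schema)
    except SchemaError as exc:
        raise RuleParseError(f"{source}: {exc}") from None
    return rs


def _parse_rule_line(line: str, schema: CohortSchema) -> Rule:
    m = re.match(r"^IF\s+(.*)\s+THEN\s+(\S+)$", line, flags=re.IGNORECASE)
    if not m:
        raise RuleParseError(f"expected 'IF ... THEN <class>', got {line!r}")
    body, cls = m.group(1), int(m.group(2))
    conditions = []
    if body.strip().upper() != "TRUE":
        for chunk in re.split(r"\s+AND\s+", body, flags=re.IGNORECASE):
            conditions.append(_parse_condition(chunk.strip(), schema))
    return Rule(tuple(conditions), consequent=cls, origin=ORIGIN_MANUAL)


def _parse_condition(text: str, schema: CohortSchema):
    for op in (LE, ">=", GT, EQ):  # match '<=' before '='
        if op in text:
            lhs, rhs = text.split(op, 1)
            if op == ">=":
                raise RuleParseError(f"operator '>=' not in the DSL (use '>'): {text!r}")
            try:
                value = float(rhs.strip())
            except ValueError:
                raise RuleParseError(f"unparseable value in {text!r}") from None
            lhs = lhs.strip()
            if "*" in lhs or "+" in lhs:
                attrs, coefs = [], []
                for term in lhs.split("+"):
                    tm = _LINEAR_TERM_RE.match(term)
                    if not tm:
                        raise RuleParseError(f"unparseable linear term {term.strip()!r}")
                    coefs.append(float(tm.group(1)))
                    attrs.append(tm.group(2))
                    schema.index(tm.group(2))  # raises SchemaError on unknown name
                return LinearCondition(tuple(attrs), tuple(coefs), op, value)
            schema.index(lhs)
            return Condition(lhs, op, value)
    raise RuleParseError(f"no operator found in condition {text!r}")


def render_ruleset(ruleset: RuleSet) -> str:
    """Canonical DSL text; ``parse_ruleset_text(render_ruleset(x))`` == x
    up to rule statistics (support/error are not serialized)."""
    lines = []
    for rule in ruleset.rules:
        body = " AND ".join(c.render() for c in rule.conditions) if rule.conditions else "TRUE"
        lines.append(f"IF {body} THEN {rule.consequent}")
    lines.append(f"DEFAULT {ruleset.default_class}")
    return "\n".join(lines) + "\n"


def perinatal_ruleset(schema: CohortSchema = None) -> RuleSet:
    """The packaged published 15-rule emergency-cesarean rule set."""
    from .schema import perinatal_schema

    schema = schema or perinatal_schema()
    ref = _importlib_resources.files("rerx.resources") / "perinatal15.rules"
    with ref.open("r", encoding="utf-8") as fh:
        return parse_ruleset_text(fh.read(), schema, source="perinatal15.rules")
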