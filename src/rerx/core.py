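"""Recursive rule extraction driver (Re-RX) with a hyperplane fallback.

One extraction round is: train a network on the current sample set, prune it
to the retained attribute sets D' (discrete) and C' (continuous), keep the
correctly-classified subset S', and induce a decision tree on S' — over D'
alone in *classic* mode, or over D' ∪ C' in *continuous* mode (the grafted
C4.5 variant, which mixes discrete equality tests and continuous thresholds
in the same antecedent). Each tree rule Ri whose support exceeds δ1 *and*
whose error exceeds δ2 is refined: the matching samples Si are re-extracted
recursively using only the discrete attributes absent from Ri's antecedent,
and Ri is replaced by the refined sub-rules prefixed with its antecedent.
When no discrete attributes remain, a separating hyperplane over the
continuous attributes is fitted instead and emitted as a pair of half-space
rules. Support and error of every emitted rule are finally recomputed on the
*original* cohort so the printed statistics refer to the population the
clinician sees.

Termination: the recursion descends only into strictly smaller subproblems
(fewer samples or a strictly smaller discrete attribute pool); a rule whose
refinement would not shrink the problem is kept as a leaf. Exceeding
``max_recursion_depth`` raises, reporting the offending rule chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigError, DegenerateInputError, RecursionDepthError
from .network import NetworkConfig, correctly_classified, prune_network, train_network
from .rules import (
    LinearCondition,
    ORIGIN_HYPERPLANE,
    Rule,
    RuleSet,
    annotate_ruleset,
    merge_conditions,
    rule_support_error,
)
from .schema import Cohort, CohortSchema, split_attributes
from .tree import TreeConfig, induce_tree, tree_to_rules

__all__ = [
    "RerxConfig",
    "Hyperplane",
    "extract_rules",
    "fit_hyperplane",
    "hyperplane_rules",
    "rule_support_error",
]

logger = logging.getLogger(__name__)

MODE_CLASSIC = "classic"
MODE_CONTINUOUS = "continuous"


@dataclass(frozen=True)
class RerxConfig:
    """Extraction thresholds and sub-stage configurations.

    ``delta1`` (support / covering rate) and ``delta2`` (error rate) jointly
    decide which rules are refined: a rule is recursed into only when it
    covers more than ``delta1`` of the samples *and* errs on more than
    ``delta2`` of those it covers.
    """

    delta1: float = 0.10
    delta2: float = 0.10
    mode: str = MODE_CONTINUOUS
    max_recursion_depth: int = 10
    network: NetworkConfig = field(default_factory=NetworkConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)

    def __post_init__(self):
        if not 0 <= self.delta1 <= 1 or not 0 <= self.delta2 <= 1:
            raise ConfigError("delta1 and delta2 must lie in [0, 1]")
        if self.mode not in (MODE_CLASSIC, MODE_CONTINUOUS):
            raise ConfigError(f"mode must be classic or continuous, got {self.mode!r}")
        if self.max_recursion_depth < 1:
            raise ConfigError("max_recursion_depth must be positive")

    def reseeded(self, seed: int) -> "RerxConfig":
        return replace(self, network=replace(self.network, seed=int(seed) % (2**31)))


@dataclass(frozen=True)
class Hyperplane:
    """Linear separator sum_i Wi * Ci = W0 over continuous attributes.

    Samples with ``sum_i Wi * Ci - W0 > 0`` fall on the positive-class side.
    Coefficients are expressed in the attributes' original units.
    """

    attribute_names: tuple
    coefficients: tuple
    intercept: float

    def __post_init__(self):
        if len(self.attribute_names) != len(self.coefficients) or not self.attribute_names:
            raise ConfigError("hyperplane needs matching attribute/coefficient lists")
        if not any(c != 0 for c in self.coefficients):
            raise ConfigError("hyperplane needs at least one nonzero coefficient")

    def decision_values(self, cohort: Cohort) -> np.ndarray:
        z = np.zeros(cohort.n)
        for a, w in zip(self.attribute_names, self.coefficients):
            z += w * cohort.column(a)
        return z - self.intercept


def fit_hyperplane(cohort: Cohort, attributes) -> Hyperplane:
    """Fit a separating hyperplane over *attributes* by logistic loss.

    Attributes are standardized internally; the returned coefficients and
    intercept are re-expressed in original units so the hyperplane reads
    directly off raw values. The fitted split always achieves training
    accuracy at least the majority-class rate (a zero-coefficient logistic
    fit already does, and the optimizer can only improve the loss).
    """
    attributes = list(attributes)
    if not attributes:
        raise ConfigError("fit_hyperplane needs at least one continuous attribute")
    pos, neg = cohort.class_counts()
    if pos == 0 or neg == 0:
        raise DegenerateInputError("hyperplane fitting requires both classes")
    A = np.column_stack([cohort.column(a) for a in attributes])
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (A - mu) / sd
    t = (cohort.y == cohort.schema.positive_label).astype(float)
    k = Z.shape[1]

    def loss_grad(theta):
        w, b = theta[:k], theta[k]
        z = Z @ w + b
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        eps = 1e-12
        ll = -np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps))
        ll += 1e-6 * np.dot(w, w)
        g = np.empty(k + 1)
        d = (p - t) / len(t)
        g[:k] = Z.T @ d + 2e-6 * w
        g[k] = d.sum()
        return ll, g

    res = minimize(loss_grad, np.zeros(k + 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    w, b = res.x[:k], res.x[k]
    if not np.any(w != 0):
        # flat fit (e.g. pure-noise data): nudge along the largest-gradient axis
        w = np.zeros(k)
        w[0] = 1e-12
    coeffs = w / sd
    intercept = float(np.dot(w, mu / sd) - b)
    return Hyperplane(tuple(attributes), tuple(coeffs), intercept)


def hyperplane_rules(hp: Hyperplane, schema: CohortSchema) -> list:
    """Render a hyperplane as its two half-space rules (<= side first)."""
    le = LinearCondition(hp.attribute_names, hp.coefficients, "<=", hp.intercept)
    gt = LinearCondition(hp.attribute_names, hp.coefficients, ">", hp.intercept)
    return [
        Rule((le,), schema.negative_label, origin=ORIGIN_HYPERPLANE),
        Rule((gt,), schema.positive_label, origin=ORIGIN_HYPERPLANE),
    ]


def extract_rules(cohort: Cohort, config: RerxConfig = None) -> RuleSet:
    """Run the full recursive extraction on a cohort.

    Returns an ordered rule set (parent rule order, then sub-tree leaf
    order) whose rules carry support and error recomputed on the input
    cohort; the default class is the cohort's majority class.
    """
    config = config or RerxConfig()
    pos, neg = cohort.class_counts()
    if pos == 0 or neg == 0:
        raise DegenerateInputError("extraction requires both classes present")
    D, C = split_attributes(cohort.schema)
    rules = _rerx(cohort, D, C, config, depth=1, chain=())
    majority = (cohort.schema.positive_label if pos > neg
                else cohort.schema.negative_label)
    ruleset = RuleSet(list(rules), default_class=majority,
                      schema_name=cohort.schema.name)
    return annotate_ruleset(ruleset, cohort)


def _leaf_rule(cohort: Cohort) -> Rule:
    pos, neg = cohort.class_counts()
    label = cohort.schema.positive_label if pos > neg else cohort.schema.negative_label
    return Rule((), label, origin="tree")


def _rerx(cohort, D_avail, C_avail, config, depth, chain):
    """One recursion level; returns a list of rules exhaustive over the
    sample space (conditions are relative to the full schema)."""
    if depth > config.max_recursion_depth:
        raise RecursionDepthError(
            "max_recursion_depth exceeded under rule chain: "
            + (" -> ".join(chain) if chain else "<root>"))
    schema = cohort.schema
    pos, neg = cohort.class_counts()
    if pos == 0 or neg == 0:
        return [_leaf_rule(cohort)]

    sub = cohort.project(list(D_avail) + list(C_avail))
    try:
        net = train_network(sub, config.network)
        net = prune_network(net, sub, config.network)
        s_prime = correctly_classified(net, sub)
    except DegenerateInputError:
        return [_leaf_rule(cohort)]
    d_ret, c_ret = net.retained_discrete, net.retained_continuous
    logger.debug("depth %d: n=%d, |D'|=%d, |C'|=%d, |S'|=%d",
                 depth, cohort.n, len(d_ret), len(c_ret), s_prime.n)

    if not d_ret:
        # D' = empty: one hyperplane over the surviving continuous
        # attributes separates S', and extraction stops on this branch
        target = s_prime if min(s_prime.class_counts()) > 0 else cohort
        return _hyperplane_or_leaf(target, c_ret or C_avail)
    tree_attrs = d_ret if config.mode == MODE_CLASSIC else d_ret + c_ret

    tree = induce_tree(s_prime, tree_attrs, config.tree)
    base_rules = tree_to_rules(tree).rules

    out = []
    for i, rule in enumerate(base_rules):
        support, error = rule_support_error(rule, cohort)
        if not (support > config.delta1 and error > config.delta2):
            out.append(rule)
            continue
        mask = rule.matches(cohort.X, schema)
        si = cohort.take(mask) if mask.any() else None
        rule_attrs = {c.attribute for c in rule.conditions
                      if not isinstance(c, LinearCondition)}
        d_i = [a for a in D_avail if a not in rule_attrs]
        shrinks = (si is not None and si.n < cohort.n) or len(d_i) < len(D_avail)
        if si is None or not shrinks:
            out.append(rule)
            continue
        si_pos, si_neg = si.class_counts()
        if si_pos == 0 or si_neg == 0:
            out.append(rule)
            continue
        tag = f"rule[{i}]@depth{depth}"
        if not d_i:
            sub_rules = _hyperplane_or_leaf(si, c_ret or C_avail)
        else:
            sub_rules = _rerx(si, d_i, C_avail, config, depth + 1, chain + (tag,))
        for sr in sub_rules:
            out.append(replace(sr, conditions=merge_conditions(
                rule.conditions + sr.conditions)))
    return out


def _hyperplane_or_leaf(cohort: Cohort, c_attrs) -> list:
    c_attrs = list(c_attrs)
    pos, neg = cohort.class_counts()
    if not c_attrs or pos == 0 or neg == 0:
        return [_leaf_rule(cohort)]
    hp = fit_hyperplane(cohort, c_attrs)
    return hyperplane_rules(hp, cohort.schema)
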