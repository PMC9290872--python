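"""Decision-tree induction: gain-ratio splits, pessimistic pruning, grafting.

This is a C4.5-style learner specialized to binary outcomes on mixed
discrete/continuous predictors, the tree stage of the rule-extraction
pipeline:

* split selection maximizes the *gain ratio* (information gain divided by
  split information, entropies in bits) among candidate splits whose gain is
  at least the mean gain of all candidates — the classic C4.5 guard against
  many-valued attributes;
* discrete attributes split multiway, one branch per declared domain code,
  and may be tested at most once per path; continuous attributes split
  binary at midpoints between consecutive distinct observed values and may
  be re-tested further down;
* grown trees are simplified by pessimistic error pruning (upper binomial
  confidence limit on the leaf error, confidence 0.25 by default);
* an optional conservative grafting pass re-splits impure leaves where a
  Laplace-corrected error comparison strictly improves, trading a slightly
  larger rule count for training accuracy (never decreasing it).

Tie-breaking is fully deterministic (higher gain ratio, then lower schema
index, then smaller threshold) so induction can be checked against
brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ConfigError, ContractError
from .rules import Condition, Rule, RuleSet, merge_conditions, ORIGIN_TREE
from .schema import CONTINUOUS, DISCRETE, Cohort, CohortSchema

__all__ = [
    "TreeConfig",
    "DecisionTree",
    "Node",
    "induce_tree",
    "gain_ratio",
    "graft_tree",
    "tree_to_rules",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TreeConfig:
    min_leaf: int = 2
    confidence: float = 0.25
    grafting: bool = True
    max_depth: int = None  # None = unbounded

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ConfigError("min_leaf must be a positive integer")
        if not 0 < self.confidence < 1:
            raise ConfigError("confidence must lie in (0, 1)")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("max_depth must be positive or None")


@dataclass
class Node:
    """Tree node. Leaves carry (label, n, errors); internal nodes carry the
    split test and children (continuous: [<=, >]; discrete: one child per
    domain code in ``codes`` order)."""

    label: int                      # majority class at this node
    n: int
    errors: int
    attribute: str = None           # None for leaves
    kind: str = None
    threshold: float = None         # continuous tests
    codes: tuple = None             # discrete tests
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def route(self, row: np.ndarray, schema: CohortSchema) -> "Node":
        if self.is_leaf:
            return self
        v = row[schema.index(self.attribute)]
        if self.kind == CONTINUOUS:
            child = self.children[0] if v <= self.threshold else self.children[1]
        else:
            try:
                child = self.children[self.codes.index(int(v))]
            except ValueError:  # code outside training domain: fall back here
                return self
        return child.route(row, schema)


@dataclass
class DecisionTree:
    root: Node
    schema: CohortSchema
    attributes: tuple            # attribute names the tree was allowed to use
    classes: tuple               # (positive_label, negative_label)
    config: TreeConfig

    @property
    def leaf_count(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def predict_row(self, row) -> int:
        return self.root.route(np.asarray(row, dtype=float), self.schema).label

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.predict_row(r) for r in X], dtype=int)

    def accuracy(self, cohort: Cohort) -> float:
        return float(np.mean(self.predict(cohort.X) == cohort.y))


# ---------------------------------------------------------------------------
# entropy machinery

def _entropy_bits(pos: float, n: float) -> float:
    if n <= 0 or pos <= 0 or pos >= n:
        return 0.0
    p = pos / n
    return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))


def _split_entropy(branch_pos, branch_n):
    """(weighted child entropy, split information), both in bits."""
    branch_pos = np.asarray(branch_pos, dtype=float)
    branch_n = np.asarray(branch_n, dtype=float)
    n = branch_n.sum()
    cond = 0.0
    split_info = 0.0
    for bp, bn in zip(branch_pos, branch_n):
        if bn > 0:
            cond += (bn / n) * _entropy_bits(bp, bn)
            split_info -= (bn / n) * np.log2(bn / n)
    return cond, float(split_info)


@dataclass(frozen=True)
class _Candidate:
    gain: float
    ratio: float
    attr_index: int              # index into the schema (for tie-breaking)
    attribute: str
    kind: str
    threshold: float = None
    codes: tuple = None


def _binary_entropy_vec(pos, n):
    pos = np.asarray(pos, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.divide(pos, n, out=np.zeros_like(pos), where=n > 0)
    out = np.zeros_like(p)
    m = (p > 0) & (p < 1)
    pm = p[m]
    out[m] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
    return out


def _candidate_splits(X, y_pos, schema, attr_names, used_discrete, min_leaf):
    """Every valid split of this node's samples, grouped per attribute:
    each discrete attribute not yet used on the path (multiway over its
    domain codes) and every midpoint threshold of each continuous attribute.
    Validity = >=2 branches holding >= min_leaf samples each.

    Returns a list of groups (dicts) ordered by schema index, each with
    vectorized ``gains``/``ratios`` arrays and either ``codes`` or ascending
    ``thresholds``.
    """
    n = X.shape[0]
    total_pos = int(y_pos.sum())
    parent_h = _entropy_bits(total_pos, n)
    groups = []
    for name in sorted(attr_names, key=schema.index):
        j = schema.index(name)
        var = schema.variable(name)
        col = X[:, j]
        if var.kind == DISCRETE:
            if name in used_discrete:
                continue
            codes = var.domain
            b_n = np.array([(col == c).sum() for c in codes], dtype=float)
            b_pos = np.array([int(y_pos[col == c].sum()) for c in codes], dtype=float)
            if (b_n >= min_leaf).sum() < 2:
                continue
            cond, si = _split_entropy(b_pos, b_n)
            gain = parent_h - cond
            if si <= _EPS:
                continue
            groups.append({"kind": DISCRETE, "attr_index": j, "attribute": name,
                           "codes": codes, "gains": np.array([gain]),
                           "ratios": np.array([gain / si])})
        else:
            order = np.argsort(col, kind="stable")
            v = col[order]
            cum_pos = np.cumsum(y_pos[order].astype(float))
            i = np.arange(1, n)  # split after position i (left size i)
            valid = (v[1:] != v[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
            idx = i[valid]
            if idx.size == 0:
                continue
            ln = idx.astype(float)
            rn = n - ln
            lp = cum_pos[idx - 1]
            rp = total_pos - lp
            cond = (ln / n) * _binary_entropy_vec(lp, ln) + (rn / n) * _binary_entropy_vec(rp, rn)
            si = -((ln / n) * np.log2(ln / n) + (rn / n) * np.log2(rn / n))
            gains = parent_h - cond
            keep = si > _EPS
            if not keep.any():
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(keep, gains / np.where(keep, si, 1.0), -np.inf)
            groups.append({"kind": CONTINUOUS, "attr_index": j, "attribute": name,
                           "gains": gains[keep], "ratios": ratios[keep],
                           "thresholds_kept": ((v[idx - 1] + v[idx]) / 2.0)[keep]})
    return groups


def _iter_candidates(groups):
    for g in groups:
        if g["kind"] == DISCRETE:
            yield _Candidate(float(g["gains"][0]), float(g["ratios"][0]),
                             g["attr_index"], g["attribute"], DISCRETE, codes=g["codes"])
        else:
            for gain, ratio, t in zip(g["gains"], g["ratios"], g["thresholds_kept"]):
                yield _Candidate(float(gain), float(ratio), g["attr_index"],
                                 g["attribute"], CONTINUOUS, threshold=float(t))


def _select_split(groups):
    """C4.5 selection: among candidates with positive gain and gain >= the
    mean gain of all candidates, maximize gain ratio; ties broken by lowest
    schema index, then smaller threshold. Returns None if no usable split."""
    if not groups:
        return None
    all_gains = np.concatenate([g["gains"] for g in groups])
    mean_gain = float(all_gains.mean())
    best = None
    for g in groups:  # schema-index order: strict '>' keeps the earliest on ties
        eligible = (g["gains"] > _EPS) & (g["gains"] >= mean_gain - _EPS)
        if not eligible.any():
            continue
        ratios = np.where(eligible, g["ratios"], -np.inf)
        k = int(np.argmax(ratios))  # first max = smallest threshold on ties
        if best is None or ratios[k] > best.ratio:
            if g["kind"] == DISCRETE:
                best = _Candidate(float(g["gains"][k]), float(ratios[k]),
                                  g["attr_index"], g["attribute"], DISCRETE,
                                  codes=g["codes"])
            else:
                best = _Candidate(float(g["gains"][k]), float(ratios[k]),
                                  g["attr_index"], g["attribute"], CONTINUOUS,
                                  threshold=float(g["thresholds_kept"][k]))
    return best


def gain_ratio(cohort: Cohort, attribute: str, test=None) -> float:
    """Gain ratio of one candidate split on a cohort.

    ``test`` is a threshold for continuous attributes (branches ``<= t`` /
    ``> t``) or ``None`` for a discrete multiway split over the domain codes.
    Raises :class:`~rerx.errors.ContractError` when the split leaves a single
    non-empty branch (split information would be zero).
    """
    schema = cohort.schema
    var = schema.variable(attribute)
    col = cohort.column(attribute)
    y_pos = cohort.y == schema.positive_label
    if var.kind == CONTINUOUS:
        if test is None:
            raise ContractError("continuous attribute needs a threshold")
        masks = [col <= test, col > test]
    else:
        masks = [col == c for c in var.domain]
    b_n = np.array([m.sum() for m in masks], dtype=float)
    if (b_n > 0).sum() < 2:
        raise ContractError("split must produce at least two non-empty branches")
    b_pos = np.array([int(y_pos[m].sum()) for m in masks], dtype=float)
    parent = _entropy_bits(int(y_pos.sum()), cohort.n)
    cond, si = _split_entropy(b_pos, b_n)
    return float((parent - cond) / si)


# ---------------------------------------------------------------------------
# induction

def induce_tree(cohort: Cohort, attributes, config: TreeConfig = None) -> DecisionTree:
    """Grow, pessimistically prune and (optionally) graft a tree.

    ``attributes`` is the subset of schema predictors the tree may test
    (D' in classic mode, D' ∪ C' in continuous mode); an empty subset is a
    contract error — the caller must route such nodes to the hyperplane
    fallback instead.
    """
    config = config or TreeConfig()
    attributes = list(attributes)
    if not attributes:
        raise ContractError("induce_tree requires a non-empty attribute set")
    for a in attributes:
        cohort.schema.index(a)
    schema = cohort.schema
    pos_label = schema.positive_label
    y_pos = cohort.y == pos_label

    def majority(idx) -> int:
        npos = int(y_pos[idx].sum())
        nneg = idx.size - npos
        # deterministic tie-break: the schema's negative (majority-prior) class
        return pos_label if npos > nneg else schema.negative_label

    def make_leaf(idx, fallback_label) -> Node:
        if idx.size == 0:
            return Node(label=fallback_label, n=0, errors=0)
        lab = majority(idx)
        err = int(np.sum(cohort.y[idx] != lab))
        return Node(label=lab, n=int(idx.size), errors=err)

    def build(idx, used_discrete, depth) -> Node:
        npos = int(y_pos[idx].sum())
        pure = npos == 0 or npos == idx.size
        if pure or idx.size < 2 * config.min_leaf or (
                config.max_depth is not None and depth >= config.max_depth):
            return make_leaf(idx, majority(idx))
        cands = _candidate_splits(cohort.X[idx], y_pos[idx], schema,
                                  attributes, used_discrete, config.min_leaf)
        best = _select_split(cands)
        if best is None:
            return make_leaf(idx, majority(idx))
        node = make_leaf(idx, majority(idx))
        node.attribute = best.attribute
        node.kind = best.kind
        col = cohort.X[idx, schema.index(best.attribute)]
        if best.kind == CONTINUOUS:
            node.threshold = best.threshold
            parts = [idx[col <= best.threshold], idx[col > best.threshold]]
            child_used = used_discrete
        else:
            node.codes = best.codes
            parts = [idx[col == c] for c in best.codes]
            child_used = used_discrete | {best.attribute}
        node.children = [
            build(part, child_used, depth + 1) if part.size else make_leaf(part, node.label)
            for part in parts
        ]
        return node

    root = build(np.arange(cohort.n), frozenset(), 0)
    root = _prune(root, config.confidence)
    tree = DecisionTree(root, schema, tuple(attributes),
                        (schema.positive_label, schema.negative_label), config)
    if config.grafting:
        tree = graft_tree(tree, cohort, config)
    return tree


# ---------------------------------------------------------------------------
# pessimistic pruning (C4.5 upper confidence limit on the binomial error)

def _pessimistic_errors(errors: int, n: int, z: float) -> float:
    if n == 0:
        return 0.0
    f = errors / n
    num = f + z * z / (2 * n) + z * np.sqrt(f / n - f * f / n + z * z / (4 * n * n))
    return n * num / (1 + z * z / n)


def _subtree_estimate(node: Node, z: float) -> float:
    return sum(_pessimistic_errors(l.errors, l.n, z) for l in node.leaves())


def _prune(node: Node, confidence: float) -> Node:
    if node.is_leaf:
        return node
    z = float(norm.ppf(1 - confidence))
    node.children = [_prune(c, confidence) for c in node.children]
    as_leaf = _pessimistic_errors(node.errors, node.n, z)
    if as_leaf <= _subtree_estimate(node, z) + 0.1:
        return Node(label=node.label, n=node.n, errors=node.errors)
    return node


# ---------------------------------------------------------------------------
# grafting

def _laplace_errors(errors: int, n: int) -> float:
    """Laplace-corrected expected errors for a binary leaf."""
    return n * (errors + 1) / (n + 2)


def graft_tree(tree: DecisionTree, cohort: Cohort, config: TreeConfig = None) -> DecisionTree:
    """Conservative post-hoc grafting pass.

    Each impure leaf with enough local evidence may be re-split (same
    candidate grammar as induction) when the split *strictly* reduces the
    sum of Laplace-corrected branch errors relative to keeping the leaf.
    Because grafted branches predict their own majority class, training-set
    accuracy never decreases and the leaf count never decreases. With
    ``config.grafting`` false the tree is returned unchanged.
    """
    config = config or tree.config
    if not config.grafting:
        return tree
    schema = tree.schema
    y_pos = cohort.y == schema.positive_label

    def walk(node: Node, idx, used_discrete) -> Node:
        if not node.is_leaf:
            j = schema.index(node.attribute)
            col = cohort.X[idx, j]
            if node.kind == CONTINUOUS:
                parts = [idx[col <= node.threshold], idx[col > node.threshold]]
                child_used = used_discrete
            else:
                parts = [idx[col == c] for c in node.codes]
                child_used = used_discrete | {node.attribute}
            node.children = [walk(c, part, child_used)
                             for c, part in zip(node.children, parts)]
            return node
        if node.n < 2 * config.min_leaf or node.errors == 0:
            return node
        groups = _candidate_splits(cohort.X[idx], y_pos[idx], schema,
                                   tree.attributes, used_discrete, config.min_leaf)
        best, best_cost = None, _laplace_errors(node.errors, node.n)
        for c in _iter_candidates(groups):
            j = schema.index(c.attribute)
            col = cohort.X[idx, j]
            if c.kind == CONTINUOUS:
                parts = [idx[col <= c.threshold], idx[col > c.threshold]]
            else:
                parts = [idx[col == code] for code in c.codes]
            cost = 0.0
            for part in parts:
                if part.size:
                    npos = int(y_pos[part].sum())
                    err = min(npos, part.size - npos)
                    cost += _laplace_errors(err, part.size)
            if cost < best_cost - _EPS:
                best, best_cost = (c, parts), cost
        if best is None:
            return node
        c, parts = best
        node.attribute, node.kind = c.attribute, c.kind
        node.threshold, node.codes = c.threshold, c.codes
        children = []
        for part in parts:
            if part.size:
                npos = int(y_pos[part].sum())
                lab = schema.positive_label if npos > part.size - npos else schema.negative_label
                children.append(Node(label=lab, n=int(part.size),
                                     errors=int(np.sum(cohort.y[part] != lab))))
            else:
                children.append(Node(label=node.label, n=0, errors=0))
        node.children = children
        return node

    walk(tree.root, np.arange(cohort.n), frozenset())
    return tree


# ---------------------------------------------------------------------------
# rule conversion

def tree_to_rules(tree: DecisionTree) -> RuleSet:
    """One rule per leaf (left-to-right), path tests merged per attribute.

    The resulting rules are mutually exclusive and exhaustive: every valid
    sample satisfies exactly one antecedent, and traversal and rule matching
    agree on its class.
    """
    rules = []

    def walk(node: Node, conds):
        if node.is_leaf:
            err = node.errors / node.n if node.n else 0.0
            rules.append(Rule(merge_conditions(conds), node.label,
                              support=None, error=err, origin=ORIGIN_TREE))
            return
        if node.kind == CONTINUOUS:
            walk(node.children[0], conds + [Condition(node.attribute, "<=", node.threshold)])
            walk(node.children[1], conds + [Condition(node.attribute, ">", node.threshold)])
        else:
            for code, child in zip(node.codes, node.children):
                walk(child, conds + [Condition(node.attribute, "=", code)])

    walk(tree.root, [])
    majority = tree.root.label
    return RuleSet(rules, default_class=majority, schema_name=tree.schema.name)
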