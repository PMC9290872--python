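"""Tree induction against brute-force gain-ratio oracles, grafting
guarantees and rule conversion."""

import math

import numpy as np
import pytest

from rerx.errors import ContractError
from rerx.rules import LinearCondition
from rerx.schema import CohortSchema, VariableSpec
from rerx.tree import TreeConfig, gain_ratio, graft_tree, induce_tree, tree_to_rules

from conftest import make_cohort, random_cohort

# ---------------------------------------------------------------------------
# independent oracle: entropy, gain and gain ratio from first principles


def oracle_entropy(labels):
    n = len(labels)
    h = 0.0
    for lab in set(labels):
        p = sum(1 for l in labels if l == lab) / n
        h -= p * math.log2(p)
    return h


def oracle_gain_splitinfo(y, branches):
    """(information gain, split information) of a partition of label list y."""
    n = len(y)
    h = oracle_entropy(y)
    cond = 0.0
    si = 0.0
    for idx in branches:
        if len(idx) == 0:
            continue
        w = len(idx) / n
        cond += w * oracle_entropy([y[i] for i in idx])
        si -= w * math.log2(w)
    return h - cond, si


def oracle_candidates(cohort, attributes, min_leaf=1):
    """Every valid split as (gain, ratio, schema index, threshold-or-None)."""
    out = []
    y = list(cohort.y)
    for name in attributes:
        j = cohort.schema.index(name)
        var = cohort.schema.variable(name)
        col = cohort.X[:, j]
        if var.kind == "discrete":
            branches = [[i for i in range(cohort.n) if col[i] == c] for c in var.domain]
            if sum(len(b) >= min_leaf for b in branches) < 2:
                continue
            gain, si = oracle_gain_splitinfo(y, branches)
            if si > 1e-12:
                out.append((gain, gain / si, j, None))
        else:
            vals = sorted(set(col))
            for lo, hi in zip(vals, vals[1:]):
                t = (lo + hi) / 2
                left = [i for i in range(cohort.n) if col[i] <= t]
                right = [i for i in range(cohort.n) if col[i] > t]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                gain, si = oracle_gain_splitinfo(y, [left, right])
                if si > 1e-12:
                    out.append((gain, gain / si, j, t))
    return out


def oracle_best_split(cohort, attributes, min_leaf=1):
    """C4.5 selection re-implemented independently: mean-gain filter then
    max gain ratio; ties -> lowest schema index, then smallest threshold."""
    cands = oracle_candidates(cohort, attributes, min_leaf)
    if not cands:
        return None
    mean_gain = sum(c[0] for c in cands) / len(cands)
    eligible = [c for c in cands if c[0] > 1e-12 and c[0] >= mean_gain - 1e-12]
    if not eligible:
        return None
    return min(eligible, key=lambda c: (-c[1], c[2],
                                        c[3] if c[3] is not None else -math.inf))


# ---------------------------------------------------------------------------


@pytest.fixture
def mixed_schema():
    return CohortSchema(
        (
            VariableSpec("d1", "discrete", (0, 1)),
            VariableSpec("c1", "continuous", (None, None)),
            VariableSpec("c2", "continuous", (None, None)),
        ),
        "y", 1, 2, name="mixed3")


class TestGainRatio:
    def test_perfect_binary_split_closed_form(self, mixed_schema):
        """A (4+,4-) node split into (4+,0-) and (0+,4-): gain = 1 bit,
        split information = 1 bit, ratio = 1."""
        X = [[0, i, 0] for i in range(4)] + [[1, 4 + i, 0] for i in range(4)]
        coh = make_cohort(mixed_schema, X, [1] * 4 + [2] * 4)
        assert gain_ratio(coh, "d1") == pytest.approx(1.0)
        assert gain_ratio(coh, "c1", 3.5) == pytest.approx(1.0)

    def test_label_independent_split_has_zero_ratio(self, mixed_schema):
        X = [[i % 2, float(i), 0] for i in range(8)]
        y = [1, 2] * 4
        coh = make_cohort(mixed_schema, X, [1, 1, 2, 2, 1, 1, 2, 2])
        assert gain_ratio(coh, "d1") == pytest.approx(0.0, abs=1e-12)

    def test_single_branch_split_rejected(self, mixed_schema):
        X = [[0, float(i), 0] for i in range(4)]
        coh = make_cohort(mixed_schema, X, [1, 2, 1, 2])
        with pytest.raises(ContractError):
            gain_ratio(coh, "d1")  # all rows share code 0
        with pytest.raises(ContractError):
            gain_ratio(coh, "c1", 100.0)  # everything on one side

    def test_matches_oracle_on_random_cohorts(self, mixed_schema):
        rng = np.random.default_rng(10)
        for trial in range(30):
            coh = random_cohort(mixed_schema, 12, rng)
            for name in mixed_schema.names:
                j = mixed_schema.index(name)
                var = mixed_schema.variable(name)
                col = coh.X[:, j]
                if var.kind == "discrete":
                    if len(set(col)) < 2:
                        continue
                    branches = [[i for i in range(coh.n) if col[i] == c]
                                for c in var.domain]
                    gain, si = oracle_gain_splitinfo(list(coh.y), branches)
                    assert gain_ratio(coh, name) == pytest.approx(gain / si)
                else:
                    vals = sorted(set(col))
                    t = (vals[0] + vals[1]) / 2
                    left = [i for i in range(coh.n) if col[i] <= t]
                    right = [i for i in range(coh.n) if col[i] > t]
                    gain, si = oracle_gain_splitinfo(list(coh.y), [left, right])
                    assert gain_ratio(coh, name, t) == pytest.approx(gain / si)


class TestInduction:
    def test_pure_cohort_gives_single_clean_leaf(self, mixed_schema):
        coh = make_cohort(mixed_schema, [[0, 1.0, 2.0], [1, 3.0, 4.0]], [2, 2])
        tree = induce_tree(coh, mixed_schema.names, TreeConfig(min_leaf=1))
        assert tree.root.is_leaf and tree.root.errors == 0
        assert tree.root.label == 2

    def test_empty_attribute_set_is_contract_error(self, mixed_schema):
        coh = make_cohort(mixed_schema, [[0, 1.0, 2.0], [1, 3.0, 4.0]], [1, 2])
        with pytest.raises(ContractError):
            induce_tree(coh, [], TreeConfig())

    def test_root_split_matches_oracle_on_random_cohorts(self, mixed_schema):
        """Acceptance-grade check: on >=100 random small cohorts the root
        split equals exhaustive gain-ratio maximization (same filter and
        tie-breaks), or the tree is a leaf exactly when the oracle finds no
        usable split."""
        rng = np.random.default_rng(11)
        checked = 0
        for trial in range(130):
            n = int(rng.integers(4, 13))
            coh = random_cohort(mixed_schema, n, rng)
            cfg = TreeConfig(min_leaf=1, grafting=False)
            tree = induce_tree(coh, mixed_schema.names, cfg)
            pure = len(set(coh.y)) == 1
            if pure or coh.n < 2:
                continue
            expected = oracle_best_split(coh, mixed_schema.names, min_leaf=1)
            if tree.root.is_leaf:
                # pessimistic pruning may collapse a genuine split; re-grow
                # without pruning interference by checking the raw chooser
                from rerx.tree import _candidate_splits, _select_split
                y_pos = coh.y == 1
                got = _select_split(_candidate_splits(
                    coh.X, y_pos, coh.schema, mixed_schema.names, frozenset(), 1))
                if expected is None:
                    assert got is None
                    continue
                assert got is not None
                got_attr, got_thr = got.attr_index, got.threshold
            else:
                got_attr = coh.schema.index(tree.root.attribute)
                got_thr = tree.root.threshold
            assert expected is not None
            exp_gain, exp_ratio, exp_attr, exp_thr = expected
            assert got_attr == exp_attr
            if exp_thr is None:
                assert got_thr is None
            else:
                assert got_thr == pytest.approx(exp_thr)
            checked += 1
        assert checked >= 100

    def test_threshold_lands_between_straddling_values(self):
        """Labels defined by birth weight > 2456 g: the induced root must be
        a depth-1 threshold on birth weight inside the straddling gap."""
        sch = CohortSchema((VariableSpec("bw", "continuous", (300.0, 6000.0)),
                            VariableSpec("other", "continuous", (None, None))),
                           "y", 1, 2)
        rng = np.random.default_rng(12)
        bw = rng.uniform(1500, 3500, 60)
        X = np.column_stack([bw, rng.normal(size=60)])
        y = np.where(bw > 2456, 2, 1)
        coh = make_cohort(sch, X, y)
        tree = induce_tree(coh, ["bw", "other"], TreeConfig(grafting=False))
        assert not tree.root.is_leaf and tree.root.attribute == "bw"
        below = bw[bw <= 2456].max()
        above = bw[bw > 2456].min()
        assert below < tree.root.threshold < above
        assert all(child.is_leaf for child in tree.root.children)

    def test_discrete_attribute_tested_once_per_path(self, mixed_schema):
        rng = np.random.default_rng(13)
        coh = random_cohort(mixed_schema, 60, rng)

        def walk(node, seen):
            if node.is_leaf:
                return
            if node.kind == "discrete":
                assert node.attribute not in seen
                seen = seen | {node.attribute}
            for c in node.children:
                walk(c, seen)

        tree = induce_tree(coh, mixed_schema.names, TreeConfig(min_leaf=1))
        walk(tree.root, set())

    def test_leaf_counts_sum_to_n_and_accuracy_beats_majority(self, mixed_schema):
        rng = np.random.default_rng(14)
        for seed in range(5):
            coh = random_cohort(mixed_schema, 40, rng, p_pos=0.3)
            tree = induce_tree(coh, mixed_schema.names, TreeConfig())
            assert sum(l.n for l in tree.root.leaves()) == coh.n
            majority = max(np.mean(coh.y == 1), np.mean(coh.y == 2))
            assert tree.accuracy(coh) >= majority


class TestGrafting:
    def _noisy_cohort(self, seed, n=80):
        sch = CohortSchema((VariableSpec("a", "continuous", (None, None)),
                            VariableSpec("b", "continuous", (None, None))),
                           "y", 1, 2)
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 2))
        y = np.where((X[:, 0] > 0) ^ (X[:, 1] > 0.3), 1, 2)
        flip = rng.random(n) < 0.1
        y = np.where(flip, 3 - y, y)
        return make_cohort(sch, X, y)

    def test_disabled_grafting_is_identity(self):
        coh = self._noisy_cohort(0)
        cfg = TreeConfig(grafting=False)
        tree = induce_tree(coh, ["a", "b"], cfg)
        before = tree_to_rules(tree)
        after = tree_to_rules(graft_tree(tree, coh, cfg))
        assert [r.conditions for r in before.rules] == [r.conditions for r in after.rules]

    @pytest.mark.parametrize("seed", range(4))
    def test_grafting_never_hurts_training_fit_or_shrinks(self, seed):
        coh = self._noisy_cohort(seed)
        plain = induce_tree(coh, ["a", "b"], TreeConfig(grafting=False))
        acc0, leaves0 = plain.accuracy(coh), plain.leaf_count
        grafted = graft_tree(plain, coh, TreeConfig(grafting=True))
        assert grafted.accuracy(coh) >= acc0
        assert grafted.leaf_count >= leaves0


class TestRuleConversion:
    def test_single_leaf_gives_always_firing_rule(self, mixed_schema):
        coh = make_cohort(mixed_schema, [[0, 1.0, 2.0], [1, 3.0, 4.0]], [2, 2])
        rs = tree_to_rules(induce_tree(coh, mixed_schema.names, TreeConfig(min_leaf=1)))
        assert len(rs) == 1 and rs.rules[0].conditions == ()

    def test_rules_partition_the_space(self, mixed_schema):
        """Every random sample satisfies exactly one rule (checked
        exhaustively, not first-match)."""
        rng = np.random.default_rng(15)
        coh = random_cohort(mixed_schema, 50, rng)
        tree = induce_tree(coh, mixed_schema.names, TreeConfig(min_leaf=1))
        rs = tree_to_rules(tree)
        probe = random_cohort(mixed_schema, 1000, rng)
        match_counts = np.zeros(probe.n, dtype=int)
        for rule in rs.rules:
            match_counts += rule.matches(probe.X, mixed_schema).astype(int)
        assert np.all(match_counts == 1)

    def test_traversal_agrees_with_matching_rule(self, mixed_schema):
        rng = np.random.default_rng(16)
        coh = random_cohort(mixed_schema, 60, rng)
        tree = induce_tree(coh, mixed_schema.names, TreeConfig())
        rs = tree_to_rules(tree)
        probe = random_cohort(mixed_schema, 300, rng)
        for row in probe.X:
            matching = [r for r in rs.rules if r.matches_row(row, mixed_schema)]
            assert len(matching) == 1
            assert matching[0].consequent == tree.predict_row(row)

    def test_same_attribute_interval_tests_are_merged(self):
        sch = CohortSchema((VariableSpec("x", "continuous", (None, None)),), "y", 1, 2)
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, 200)
        y = np.where(x <= 3, 1, np.where(x <= 7, 2, 1))  # forces nested splits
        coh = make_cohort(sch, np.c_[x], y)
        rs = tree_to_rules(induce_tree(coh, ["x"], TreeConfig(grafting=False)))
        for rule in rs.rules:
            ops = [(c.attribute, c.op) for c in rule.conditions
                   if not isinstance(c, LinearCondition)]
            assert len(ops) == len(set(ops))  # at most one <= and one > per attr
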