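"""Performance harness: repeated stratified k-fold CV, accuracy, AUC.

The evaluation protocol for rule extraction in this package is repeated
stratified cross-validation of the *entire* pipeline: within each fold the
rules are extracted from the training split alone and scored on the held-out
fold, so the reported test accuracy reflects generalization of the extracted
rule set, not of the underlying network.

Because a hard rule classifier emits classes rather than probabilities, ROC
analysis needs a scoring convention. Each sample is scored by the rule that
fires for it: ``1 − error`` when the rule predicts the positive class and
``error`` when it predicts the negative class (rule errors having been
estimated on the training split); samples falling through to the default
class score 0.5. Any strictly monotone transform of these scores leaves the
AUC unchanged, so the convention only orders samples by how confidently
their rule points at the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import RerxConfig, extract_rules
from .errors import ContractError, DegenerateInputError
from .rules import RuleSet, apply_ruleset_cohort
from .schema import Cohort

__all__ = ["CVReport", "crossvalidate", "accuracy", "auc", "score_samples"]


def accuracy(predictions, labels) -> float:
    """Fraction of exact matches between two equal-length class-code vectors."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ContractError("predictions and labels must have equal nonzero length")
    return float(np.mean(predictions == labels))


def auc(scores, labels, positive_label=1) -> float:
    """Area under the ROC curve as the tie-aware Mann-Whitney estimate.

    Equals the probability that a uniformly chosen positive sample scores
    above a uniformly chosen negative one, counting ties one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUC is undefined with a single class")
    ranks = rankdata(scores)  # midranks: ties counted 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def score_samples(ruleset: RuleSet, cohort: Cohort) -> np.ndarray:
    """Positive-class scores under the fired-rule convention (see module doc)."""
    _, fired = apply_ruleset_cohort(ruleset, cohort)
    pos_label = cohort.schema.positive_label
    scores = np.full(cohort.n, 0.5)
    for i, rule in enumerate(ruleset.rules):
        m = fired == i
        if not m.any():
            continue
        err = rule.error if rule.error is not None else 0.0
        scores[m] = 1.0 - err if rule.consequent == pos_label else err
    return scores


@dataclass
class CVReport:
    """Per-cell records and aggregates of repeated k-fold cross-validation."""

    runs: int
    folds: int
    seed: int
    records: list = field(default_factory=list)  # dicts per run x fold

    def _col(self, key):
        return np.array([r[key] for r in self.records], dtype=float)

    @property
    def mean_train_accuracy(self) -> float:
        return float(self._col("train_accuracy").mean())

    @property
    def mean_test_accuracy(self) -> float:
        return float(self._col("test_accuracy").mean())

    @property
    def mean_rule_count(self) -> float:
        return float(self._col("rule_count").mean())

    @property
    def mean_auc(self) -> float:
        return float(self._col("auc").mean())

    def summary(self) -> dict:
        out = {"runs": self.runs, "folds": self.folds, "seed": self.seed}
        for key in ("train_accuracy", "test_accuracy", "rule_count",
                    "conditions_per_rule", "auc"):
            col = self._col(key)
            out[f"mean_{key}"] = float(col.mean())
            out[f"sd_{key}"] = float(col.std(ddof=1)) if col.size > 1 else 0.0
        return out


def stratified_folds(y, positive_label, folds, rng):
    """Fold assignment (array of fold ids) preserving class proportions."""
    n = len(y)
    assign = np.empty(n, dtype=int)
    for cls_mask in (np.asarray(y) == positive_label, np.asarray(y) != positive_label):
        idx = np.flatnonzero(cls_mask)
        idx = rng.permutation(idx)
        for f, part in enumerate(np.array_split(idx, folds)):
            assign[part] = f
    return assign


def crossvalidate(cohort: Cohort, config: RerxConfig = None, folds: int = 5,
                  runs: int = 10, seed: int = 0, stratified: bool = True) -> CVReport:
    """Repeated k-fold cross-validation of the full extraction pipeline.

    Each run draws a fresh fold assignment from a seed derived from *seed*;
    within each fold ``extract_rules`` sees the training split only. The
    aggregate means are taken over all ``runs x folds`` cells. Fully
    reproducible for a fixed (cohort, config, seed).
    """
    config = config or RerxConfig()
    if folds < 2:
        raise ContractError("folds must be >= 2")
    pos, neg = cohort.class_counts()
    if min(pos, neg) < folds:
        raise DegenerateInputError(
            f"stratification infeasible: minority class has {min(pos, neg)} "
            f"members for {folds} folds")
    report = CVReport(runs=runs, folds=folds, seed=seed)
    pos_label = cohort.schema.positive_label
    for run in range(runs):
        run_seed = (seed * 100003 + run * 101) % (2**31)
        rng = np.random.default_rng(run_seed)
        if stratified:
            assign = stratified_folds(cohort.y, pos_label, folds, rng)
        else:
            assign = rng.permutation(np.arange(cohort.n) % folds)
        for f in range(folds):
            test_mask = assign == f
            train = cohort.take(~test_mask)
            test = cohort.take(test_mask)
            fold_cfg = config.reseeded(run_seed + 7 * f + 1)
            ruleset = extract_rules(train, fold_cfg)
            train_pred, _ = apply_ruleset_cohort(ruleset, train)
            test_pred, _ = apply_ruleset_cohort(ruleset, test)
            try:
                fold_auc = auc(score_samples(ruleset, test), test.y, pos_label)
            except DegenerateInputError:
                fold_auc = np.nan
            report.records.append({
                "run": run,
                "fold": f,
                "train_accuracy": accuracy(train_pred, train.y),
                "test_accuracy": accuracy(test_pred, test.y),
                "rule_count": len(ruleset),
                "conditions_per_rule": float(np.mean(
                    [r.n_conditions for r in ruleset.rules])),
                "auc": fold_auc,
            })
    return report
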