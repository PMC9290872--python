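"""Small feedforward classifier with attribute-level pruning.

The first stage of recursive rule extraction trains a single-hidden-layer
network on the full cohort and then *prunes input attributes*: predictors
whose removal does not cost training accuracy are eliminated, leaving the
retained discrete set D' and continuous set C' that the tree stage consumes.
The correctly-classified subset S' of the training data is what the tree is
induced on, so the network acts as both a feature filter and a label filter.

Architecture: p inputs -> H tanh hidden units -> 1 logistic output, trained
by deterministic full-batch gradient descent with classical momentum on the
cross-entropy loss with an L2 penalty. Continuous inputs are z-scored on the
training data; the standardization constants are stored in the network so
later predictions reuse them.

Pruning is greedy backward elimination at the attribute level: at each step
the candidate whose zeroed-out removal degrades training accuracy least is
chosen (evaluated with forward passes only); if that already stays within
``prune_tolerance`` of the current accuracy the removal is accepted
outright, otherwise the network is briefly retrained without the attribute
and the tolerance re-checked. The loop stops at the first rejected removal,
so accuracy after any accepted step is >= (accuracy before the step −
prune_tolerance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DegenerateInputError, TrainingError
from .schema import CONTINUOUS, Cohort, CohortSchema

__all__ = [
    "NetworkConfig",
    "PrunedNetwork",
    "train_network",
    "prune_network",
    "correctly_classified",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Training and pruning hyperparameters.

    The defaults are deliberately small-scale: cohorts in this setting have
    O(10^3) rows and O(10) informative predictors, for which 4 hidden units
    and a few hundred full-batch epochs are ample.
    """

    hidden_units: int = 4
    max_epochs: int = 400
    learning_rate: float = 0.2
    momentum: float = 0.9
    l2_penalty: float = 1e-4
    prune_tolerance: float = 0.01
    retrain_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1 or self.max_epochs < 1 or self.retrain_epochs < 1:
            raise ConfigError("hidden_units, max_epochs, retrain_epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.l2_penalty < 0:
            raise ConfigError("l2_penalty must be non-negative")
        if not 0 <= self.prune_tolerance < 1:
            raise ConfigError("prune_tolerance must lie in [0, 1)")
        if not 0 <= self.momentum < 1:
            raise ConfigError("momentum must lie in [0, 1)")


@dataclass
class PrunedNetwork:
    """Trained network plus retained attribute sets.

    ``mask`` marks retained input attributes; masked attributes have their
    input weights zeroed, so an attribute is retained iff at least one of its
    input->hidden weights is nonzero.
    """

    schema: CohortSchema
    W1: np.ndarray            # (p, H)
    b1: np.ndarray            # (H,)
    W2: np.ndarray            # (H,)
    b2: float
    mu: np.ndarray            # (p,) standardization shift
    sigma: np.ndarray         # (p,) standardization scale
    mask: np.ndarray          # (p,) bool
    training_accuracy: float
    config: NetworkConfig

    @property
    def retained(self) -> list:
        return [v.name for v, keep in zip(self.schema.variables, self.mask) if keep]

    @property
    def retained_discrete(self) -> list:
        return [n for n in self.retained if self.schema.variable(n).kind != CONTINUOUS]

    @property
    def retained_continuous(self) -> list:
        return [n for n in self.retained if self.schema.variable(n).kind == CONTINUOUS]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Pre-sigmoid output for raw-unit inputs."""
        Z = (np.asarray(X, dtype=float) - self.mu) / self.sigma
        Z = Z * self.mask
        H = np.tanh(Z @ self.W1 + self.b1)
        return H @ self.W2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class codes (positive where the output unit exceeds 1/2)."""
        pos = self.decision_values(X) > 0.0
        return np.where(pos, self.schema.positive_label, self.schema.negative_label)

    def accuracy(self, cohort: Cohort) -> float:
        return float(np.mean(self.predict(cohort.X) == cohort.y))


def _standardizers(cohort: Cohort):
    mu = np.zeros(cohort.p)
    sigma = np.ones(cohort.p)
    for j, var in enumerate(cohort.schema.variables):
        if var.kind == CONTINUOUS:
            col = cohort.X[:, j]
            mu[j] = col.mean()
            s = col.std()
            sigma[j] = s if s > 0 else 1.0
    return mu, sigma


def _fit(Z, t, W1, b1, W2, b2, mask, epochs, config):
    """Momentum gradient descent on cross-entropy + L2; returns new params."""
    n = Z.shape[0]
    Zm = Z * mask
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = 0.0
    lr, mom, l2 = config.learning_rate, config.momentum, config.l2_penalty
    for epoch in range(epochs):
        A = Zm @ W1 + b1
        H = np.tanh(A)
        out = H @ W2 + b2
        p = 1.0 / (1.0 + np.exp(-out))
        if not np.all(np.isfinite(p)):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        d_out = (p - t) / n                      # dL/d_out
        gW2 = H.T @ d_out + l2 * W2
        gb2 = d_out.sum()
        d_hidden = np.outer(d_out, W2) * (1.0 - H * H)
        gW1 = Zm.T @ d_hidden + l2 * W1
        gb1 = d_hidden.sum(axis=0)
        vW1 = mom * vW1 - lr * gW1
        vb1 = mom * vb1 - lr * gb1
        vW2 = mom * vW2 - lr * gW2
        vb2 = mom * vb2 - lr * gb2
        W1 = W1 + vW1
        b1 = b1 + vb1
        W2 = W2 + vW2
        b2 = b2 + vb2
    W1 = W1 * mask[:, None]  # keep masked weights exactly zero
    return W1, b1, W2, b2


def train_network(cohort: Cohort, config: NetworkConfig) -> PrunedNetwork:
    """Train the classifier on all attributes (nothing pruned yet).

    Deterministic under ``config.seed``. Raises
    :class:`~rerx.errors.DegenerateInputError` if the cohort holds a single
    class and :class:`~rerx.errors.TrainingError` if the loss diverges.
    """
    pos, neg = cohort.class_counts()
    if pos == 0 or neg == 0:
        raise DegenerateInputError("training requires both classes present")
    mu, sigma = _standardizers(cohort)
    Z = (cohort.X - mu) / sigma
    t = (cohort.y == cohort.schema.positive_label).astype(float)
    rng = np.random.default_rng(config.seed)
    H = config.hidden_units
    W1 = rng.normal(0.0, 1.0 / np.sqrt(cohort.p), size=(cohort.p, H))
    b1 = np.zeros(H)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(H), size=H)
    b2 = 0.0
    mask = np.ones(cohort.p, dtype=bool)
    W1, b1, W2, b2 = _fit(Z, t, W1, b1, W2, b2, mask, config.max_epochs, config)
    net = PrunedNetwork(cohort.schema, W1, b1, W2, b2, mu, sigma, mask, 0.0, config)
    net.training_accuracy = net.accuracy(cohort)
    return net


def _masked_accuracy_all_candidates(net: PrunedNetwork, Z, t) -> np.ndarray:
    """Training accuracy after zeroing each retained attribute (no retrain).

    Computed incrementally: dropping attribute j shifts every hidden
    pre-activation by -Z[:, j] * W1[j], so all candidates are evaluated with
    one base forward pass plus one rank-1 correction per candidate.
    """
    Zm = Z * net.mask
    A = Zm @ net.W1 + net.b1
    accs = np.full(len(net.mask), -1.0)
    for j in np.flatnonzero(net.mask):
        Aj = A - np.outer(Z[:, j], net.W1[j])
        out = np.tanh(Aj) @ net.W2 + net.b2
        accs[j] = np.mean((out > 0) == (t > 0.5))
    return accs


def prune_network(net: PrunedNetwork, cohort: Cohort, config: NetworkConfig = None) -> PrunedNetwork:
    """Greedy attribute-level backward elimination (see module docstring).

    Returns a new network; the retained set never grows, and training
    accuracy after each accepted step stays within ``prune_tolerance`` of the
    accuracy before that step.
    """
    config = config or net.config
    if not 0 <= config.prune_tolerance < 1:
        raise ConfigError("prune_tolerance must lie in [0, 1)")
    Z = (cohort.X - net.mu) / net.sigma
    t = (cohort.y == cohort.schema.positive_label).astype(float)
    net = replace(net)
    net.mask = net.mask.copy()
    net.W1 = net.W1.copy()
    acc = net.accuracy(cohort)
    while net.mask.sum() > 1:
        cand = _masked_accuracy_all_candidates(net, Z, t)
        j = int(np.argmax(cand))          # ties -> lowest index
        if cand[j] >= acc - config.prune_tolerance:
            net.mask[j] = False
            net.W1[j] = 0.0
            acc = float(cand[j])
            continue
        # zero-out alone too costly: brief retraining without attribute j
        trial_mask = net.mask.copy()
        trial_mask[j] = False
        W1, b1, W2, b2 = _fit(Z, t, net.W1, net.b1, net.W2, net.b2,
                              trial_mask, config.retrain_epochs, config)
        out = np.tanh((Z * trial_mask) @ W1 + b1) @ W2 + b2
        new_acc = float(np.mean((out > 0) == (t > 0.5)))
        if new_acc >= acc - config.prune_tolerance:
            net.mask = trial_mask
            net.W1, net.b1, net.W2, net.b2 = W1, b1, W2, b2
            acc = new_acc
        else:
            break
    net.training_accuracy = net.accuracy(cohort)
    return net


def correctly_classified(net: PrunedNetwork, cohort: Cohort) -> Cohort:
    """The sub-cohort S' of rows the network labels correctly."""
    keep = net.predict(cohort.X) == cohort.y
    if not keep.any():
        # preserve Cohort's n >= 1 invariant by returning an empty marker
        raise DegenerateInputError("network classifies no sample correctly")
    return cohort.take(keep)


# ---------------------------------------------------------------------------
# JSON serialization (for the train/extract CLI round trip)

def save_network(net: PrunedNetwork, path) -> Path:
    doc = {
        "schema_name": net.schema.name,
        "variables": net.schema.names,
        "W1": net.W1.tolist(),
        "b1": net.b1.tolist(),
        "W2": net.W2.tolist(),
        "b2": float(net.b2),
        "mu": net.mu.tolist(),
        "sigma": net.sigma.tolist(),
        "mask": net.mask.astype(int).tolist(),
        "training_accuracy": net.training_accuracy,
        "config": {k: getattr(net.config, k) for k in NetworkConfig.__dataclass_fields__},
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path


def load_network(path, schema: CohortSchema) -> PrunedNetwork:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc["variables"] != schema.names:
        raise ConfigError("network was trained under a different schema")
    return PrunedNetwork(
        schema,
        np.asarray(doc["W1"], dtype=float),
        np.asarray(doc["b1"], dtype=float),
        np.asarray(doc["W2"], dtype=float),
        float(doc["b2"]),
        np.asarray(doc["mu"], dtype=float),
        np.asarray(doc["sigma"], dtype=float),
        np.asarray(doc["mask"], dtype=bool),
        float(doc["training_accuracy"]),
        NetworkConfig(**doc["config"]),
    )
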