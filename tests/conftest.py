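import numpy as np
import pytest

from rerx.schema import Cohort, CohortSchema, VariableSpec


@pytest.fixture(scope="session")
def perinatal():
    from rerx.schema import perinatal_schema

    return perinatal_schema()


@pytest.fixture(scope="session")
def table15(perinatal):
    from rerx.rules import perinatal_ruleset

    return perinatal_ruleset(perinatal)


@pytest.fixture
def two_var_schema():
    """One discrete + one continuous predictor; classes 1 (pos) / 2 (neg)."""
    return CohortSchema(
        (
            VariableSpec("flag", "discrete", (0, 1)),
            VariableSpec("x", "continuous", (None, None)),
        ),
        outcome_name="y",
        positive_label=1,
        negative_label=2,
        name="toy2",
    )


def make_cohort(schema, X, y):
    return Cohort(schema, np.asarray(X, dtype=float), np.asarray(y, dtype=int))


def random_cohort(schema, n, rng, p_pos=0.5):
    """Rows uniform over each variable's (bounded) domain; labels Bernoulli."""
    X = np.empty((n, schema.p))
    for j, var in enumerate(schema.variables):
        if var.kind == "discrete":
            X[:, j] = rng.choice(var.domain, size=n)
        else:
            lo, hi = var.domain
            lo = -10.0 if lo is None else lo
            hi = 10.0 if hi is None else hi
            X[:, j] = rng.uniform(lo, hi, size=n)
    y = np.where(rng.random(n) < p_pos, schema.positive_label, schema.negative_label)
    # ensure both classes where possible
    if n >= 2 and len(set(y)) == 1:
        y[0] = schema.positive_label if y[0] == schema.negative_label else schema.negative_label
    return make_cohort(schema, X, y)
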