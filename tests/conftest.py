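import numpy as np
import pandas as pd
import pytest

from bingeclass import generate_cohort, published_classifier
from bingeclass.survey import ITEM_FIELDS, RETAINED_ITEMS

# Published cluster means on the five retained items (classifier order:
# six-drink frequency, speed, drunkenness frequency, drunk/10, hangover/10).
CLUSTER_MEANS_RETAINED = {
    1: (0.90, 1.47, 0.93, 1.24, 1.23),
    2: (1.89, 2.32, 5.82, 4.95, 4.15),
    3: (2.66, 2.85, 19.28, 6.10, 4.65),
    4: (2.65, 3.17, 39.26, 6.52, 3.94),
}

# All seven items, canonical ITEM_FIELDS order.
CLUSTER_MEANS_FULL = {
    1: (1.79, 0.70, 0.90, 1.47, 0.93, 1.24, 1.23),
    2: (2.19, 1.54, 1.89, 2.32, 5.82, 4.95, 4.15),
    3: (2.60, 2.04, 2.66, 2.85, 19.28, 6.10, 4.65),
    4: (3.02, 2.76, 2.65, 3.17, 39.26, 6.52, 3.94),
}


@pytest.fixture(scope="session")
def published():
    return published_classifier()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-profile cohort shared across tests (seed 7)."""
    cohort, labels = generate_cohort(n=3000, seed=7)
    return cohort, labels


def sample_groups_from(model, X, seed):
    """Sample ordinal outcomes from a model's category probabilities.

    Uses a stream independent of any cohort-generation seed.
    """
    rng = np.random.default_rng(10**6 + seed)
    probs = model.predict_proba(X)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(probs))
    return 1 + (u[:, None] > cum[:, :-1]).sum(axis=1)


def numerical_gradient(f, theta, h=1e-6):
    """Central-difference gradient, the independent oracle for the score."""
    g = np.empty_like(theta)
    for i in range(len(theta)):
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


def valid_raw_record(**overrides):
    base = {
        "id": "r1",
        "gender": "F",
        "age": 21,
        "consumption_frequency": 2,
        "drinks_typical_day": 1,
        "six_drink_frequency": 1,
        "consumption_speed": 1.5,
        "drunkenness_frequency": 3,
        "drunk_per_10": 2.0,
        "hangover_per_10": 1.0,
    }
    base.update(overrides)
    return base
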