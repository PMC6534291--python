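import numpy as np
import pytest

from fundustda.persistence import PersistenceDiagram
from fundustda.pipeline import PipelineConfig, classify_table, cohort_table
from fundustda.synthetic import SyntheticConfig, generate_cohort


def make_diagram(pairs, dimension=0, essential=None):
    pairs = np.asarray(pairs, dtype=np.float64).reshape(-1, 2)
    if essential is None:
        essential = np.zeros(len(pairs), dtype=bool)
    return PersistenceDiagram(dimension, pairs, essential)


def random_diagram(rng, n, scale=3.0):
    b = rng.uniform(-scale, scale, n)
    d = b + rng.uniform(0.0, scale, n)
    return make_diagram(np.stack([b, d], axis=1))


@pytest.fixture(scope="session")
def strong_cohort_table():
    """Feature table of the default strong-effect synthetic cohort.

    15 + 15 fields of 128 x 128 at a fixed seed; built once per session
    because the full persistence pipeline over 30 fields takes some
    seconds.
    """
    config = SyntheticConfig(seed=20260927)
    fields, manifest = generate_cohort(config)
    return cohort_table(fields, manifest)


@pytest.fixture(scope="session")
def small_cohort_table():
    """Tiny 3 + 3 cohort of 32 x 32 fields for fast classifier smoke tests."""
    config = SyntheticConfig(height=32, width=32, n_per_group=3, seed=11)
    fields, manifest = generate_cohort(config)
    return cohort_table(fields, manifest)
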