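import warnings

import numpy as np
import pytest

from tnbcprog.synthetic import CohortConfig, generate_cohort

SMALL_COHORT_KW = dict(
    datasets={"train": 150, "testA": 60, "testB": 50},
    baselines={"train": (1.1, 18.0), "testA": (0.9, 14.0), "testB": (1.3, 25.0)},
    n_signatures=40,
    n_mutation_genes=60,
    n_tp53_variants=15,
    n_segments=25,
    n_subtype_genes=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced multi-dataset cohort shared by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig(**SMALL_COHORT_KW))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
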