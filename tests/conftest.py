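import numpy as np
import pytest

from trwmap.pipeline import run_full
from trwmap.segmentation import gen_segmentation


@pytest.fixture(scope="session")
def default_spec():
    """Default three-level segmentation of a 255 s stimulus."""
    return gen_segmentation(255.0, seed=11)


@pytest.fixture(scope="session")
def small_spec():
    """Tiny two-level segmentation for fast audio tests."""
    return gen_segmentation(
        12.0, {"measure": (1.0, 0.1), "phrase": (4.0, 0.5)}, seed=3
    )


@pytest.fixture(scope="session")
def full_pipeline():
    """One complete synthetic experiment at the default study conditions.

    15 subjects, alpha/sigma = 1, 12^3 grid, 500 phase-randomization
    replicates. Shared across the tests that examine recovery, profiles,
    and map topology, because it is by far the most expensive fixture.
    """
    return run_full(seed=7, n_perm=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
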