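import numpy as np
import pandas as pd
import pytest

from parallelpy.datatypes import CountMatrix, SampleDesign
from parallelpy.synthetic import make_study_design


@pytest.fixture
def small_design() -> SampleDesign:
    """1 evolved population (3 reps) vs 5 ancestral samples."""
    return make_study_design(n_pops=1, n_reps=3, n_ancestral=5)


@pytest.fixture
def study_design() -> SampleDesign:
    """The full 10-population x 3-replicate + 5-ancestral layout."""
    return make_study_design()


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = np.array(
        [[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 2, 3]], dtype=np.int64
    )
    return CountMatrix(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], counts)


def nb_counts(rng, mu, phi, shape):
    """Gamma-Poisson NB sampler used as an independent draw in tests."""
    if np.all(np.asarray(phi) <= 0):
        return rng.poisson(mu, shape)
    lam = rng.gamma(1.0 / phi, np.broadcast_to(phi * mu, shape))
    return rng.poisson(lam)
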