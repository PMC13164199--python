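import numpy as np
import pandas as pd
import pytest

from chemocal import RunConfig, run_all
from chemocal.synthetic import StudyDesign


@pytest.fixture(scope="session")
def default_bundle():
    """One full default run (both ranges, both indices, 200-iteration
    permutation validation of every best model), shared across tests."""
    return run_all(RunConfig(seed=1), run_permutation=True)


@pytest.fixture
def design():
    return StudyDesign(seed=123)


@pytest.fixture
def small_design():
    """Reduced acquisition (2 subsamples x 3 scans) for fast classifier tests."""
    return StudyDesign(n_subsamples=2, n_scans_per_subsample=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)
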