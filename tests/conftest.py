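import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from apatrace.synthetic_data import SimDesign, make_annotation, simulate_pa_counts


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(n_genes=30, library_size=30_000, seed=11, uarna_rate=0.4)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """(genes, genome, truth matrix) for a 30-gene simulation."""
    genes, genome = make_annotation(small_design)
    matrix = simulate_pa_counts(genes, small_design)
    return genes, genome, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
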