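import numpy as np
import pytest

from ensemblesdm import derive_bioclim, generate_climate, generate_virtual_species
from ensemblesdm.grid import Grid


@pytest.fixture(scope="session")
def small_climate():
    """A 12x12 current climate plus 2 models x 2 scenarios of futures."""
    current_mcf, future_mcfs = generate_climate((12, 12), 2, 2, seed=7)
    current = derive_bioclim(current_mcf)
    futures = [derive_bioclim(f, grid=current.grid) for f in future_mcfs]
    return current, futures


@pytest.fixture(scope="session")
def small_species(small_climate):
    current, _ = small_climate
    species, occ = generate_virtual_species(3, current, seed=7)
    return species, occ


@pytest.fixture()
def grid5():
    return Grid(n_rows=5, n_cols=5, cell_size=1.0, origin=(0.0, 5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
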