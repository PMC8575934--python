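import numpy as np
import pytest

from chirosense.preprocessing import SpectralBlock
from chirosense.spectra_io import Spectrum, WavelengthGrid, default_grid
from chirosense.synthetic import NoiseModel, simulate_design


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cd_spectrum(grid, rng):
    return Spectrum(
        grid=grid,
        intensities=rng.normal(size=len(grid)),
        modality="CD",
        solvent="DCE",
        sample_id="s1",
    )


@pytest.fixture
def quaternary_noiseless():
    """8 noiseless quaternary mixtures: rank-4 fused structure."""
    return simulate_design("quaternary", 8, 0, seed=7)


@pytest.fixture
def quaternary_campaign():
    """16 train + 5 test with default noise (the scaled-down benchmark design)."""
    return simulate_design("quaternary", 16, 5, seed=3, noise=NoiseModel(seed=3))


@pytest.fixture
def octonary_campaign():
    return simulate_design("octonary", 24, 6, seed=3, noise=NoiseModel(seed=3))


def random_block(rng, n=10, p=20, name=("CD", "DCE"), grid_start=300.0):
    g = WavelengthGrid(np.arange(grid_start, grid_start + p, 1.0))
    return SpectralBlock(
        name=name,
        matrix=rng.normal(size=(n, p)),
        grid=g,
        sample_ids=[f"s{i}" for i in range(n)],
    )
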