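import numpy as np
import pytest

from seiralab.absorber import (AbsorberConfig, DEFAULT_CALIBRATION,
                               length_sweep)
from seiralab.pca import build_grid, interpret_scores, run_pca, simulate_design
from seiralab.permittivity import MixtureSpec


@pytest.fixture(scope="session")
def config():
    return AbsorberConfig()


@pytest.fixture(scope="session")
def cal():
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def fine_grid():
    """5 nm analysis grid used for anticrossing sweeps."""
    return build_grid(3000.0, 7000.0, 5.0)


@pytest.fixture(scope="session")
def anticrossing_sweep(config, cal, fine_grid):
    """Length sweep of the standard equal mixture across both bands."""
    return length_sweep(config, MixtureSpec(0.5, 1.0),
                        np.linspace(1.23, 1.43, 41), fine_grid, cal)


@pytest.fixture(scope="session")
def design_dataset():
    """Noiseless ten-condition design on the acquisition grid."""
    return simulate_design()


@pytest.fixture(scope="session")
def design_pca(design_dataset):
    return run_pca(design_dataset)


@pytest.fixture(scope="session")
def design_zoning(design_pca, design_dataset):
    return interpret_scores(design_pca, design_dataset.mixtures)
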