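"""Shared fixtures: grids, a reference material, forward-simulated PSDs."""

import numpy as np
import pytest
from scipy.stats import norm

from jetpbm.pbm_core import PSD, ProcessSettings, make_grid
from jetpbm.synthetic_data import default_material_library, gen_unmilled_psd


@pytest.fixture(scope="session")
def grid():
    """Default-resolution model grid."""
    return make_grid(0.1, 500.0, 80)


@pytest.fixture(scope="session")
def coarse_grid():
    """Reduced grid for optimization-heavy tests."""
    return make_grid(0.1, 500.0, 40)


@pytest.fixture(scope="session")
def material():
    """A mid-size grade from the default library (median 36 um)."""
    return default_material_library()[5]


@pytest.fixture(scope="session")
def settings():
    return ProcessSettings(gfr=2.2, mfr=5.0)


@pytest.fixture(scope="session")
def unmilled(material, grid):
    return gen_unmilled_psd(material, grid, seed=0)


@pytest.fixture(scope="session")
def unmilled_coarse(material, coarse_grid):
    return gen_unmilled_psd(material, coarse_grid, seed=0)


def lognormal_psd(grid, median, sigma_log):
    """Discretized log-normal volume PSD (helper, not a fixture)."""
    z = (np.log(grid.edges) - np.log(median)) / sigma_log
    return PSD.from_volume(grid, np.diff(norm.cdf(z)))
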