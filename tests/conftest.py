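import numpy as np
import pytest

from seeddisp.kernels import DispersalKernel, DispersalParams
from seeddisp.population import StudyWindow
from seeddisp.simulate import (draw_founder_genotypes, simulate_adults,
                               simulate_allele_frequencies)


@pytest.fixture(scope="session")
def window():
    return StudyWindow.rectangle(2000.0, 2000.0)


@pytest.fixture(scope="session")
def afreq17():
    """17 microsatellite loci with 8 alleles each, moderately uneven."""
    return simulate_allele_frequencies(17, 8, concentration=1.0, seed=101)


@pytest.fixture(scope="session")
def adults(window, afreq17):
    """~100 genotyped dioecious adults in the 2 km x 2 km window."""
    raw = simulate_adults(window, intensity=100 / window.area, seed=102)
    return draw_founder_genotypes(raw, afreq17, seed=103)


@pytest.fixture(scope="session")
def gaussian_params():
    """Seed displacements ~ 2-D isotropic normal, sd 300 m per axis
    (exponential power b = 2, mean distance 300 * sqrt(pi/2))."""
    return DispersalParams(seed=DispersalKernel(300.0 * np.sqrt(np.pi / 2), 2.0),
                           pollen=DispersalKernel(300.0, 1.0))
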