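import numpy as np
import pytest

from spectroqtl.spectrum import CANONICAL_GRID, Spectrum
from spectroqtl.synthetic import (
    DEFAULT_COMPONENT_MEANS,
    PanelDesign,
    default_component_models,
    simulate_ri_genotypes,
    synthesize_spectrum,
    vapor_reference_spectrum,
)


@pytest.fixture(scope="session")
def grid():
    return CANONICAL_GRID


@pytest.fixture(scope="session")
def vapor_ref():
    return vapor_reference_spectrum()


@pytest.fixture(scope="session")
def adipose_models():
    return default_component_models("adipose")


@pytest.fixture(scope="session")
def adipose_means():
    return dict(DEFAULT_COMPONENT_MEANS["adipose"])


@pytest.fixture
def clean_adipose(adipose_models, adipose_means):
    """Artifact-free adipose spectrum at the default component means."""
    return synthesize_spectrum(adipose_means, adipose_models, tissue="adipose")


@pytest.fixture
def zero_spectrum(grid):
    return Spectrum(grid.copy(), np.zeros_like(grid))


@pytest.fixture(scope="session")
def small_panel():
    """A fixed 30-strain, 3-chromosome panel used across QTL tests."""
    design = PanelDesign(
        n_strains=30,
        chrom_lengths_cm={"1": 60.0, "2": 60.0, "3": 60.0},
        marker_spacing_cm=5.0,
        seed=11,
    )
    return simulate_ri_genotypes(design)


def gaussian_spectrum(center, sigma, amplitude=1.0):
    """Single-Gaussian spectrum on the canonical grid."""
    g = CANONICAL_GRID
    return Spectrum(g.copy(), amplitude * np.exp(-((g - center) ** 2) / (2 * sigma**2)))
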