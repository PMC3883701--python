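import numpy as np
import pytest

from teloquant import gelsim


@pytest.fixture
def mig():
    """Reference migration model: d = 60 - 40*log10(size_kb)."""
    return gelsim.MigrationModel(a_mm=60.0, b_mm_per_decade=40.0)


@pytest.fixture
def point_mass_grid():
    """Helper building a single-fragment distribution at a given size."""

    def build(size_bp: int) -> gelsim.FragmentSizeDistribution:
        grid = np.array([size_bp - 100, size_bp, size_bp + 100])
        ab = np.array([0.0, 1.0, 0.0])
        return gelsim.FragmentSizeDistribution(sizes_bp=grid, abundance=ab)

    return build
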