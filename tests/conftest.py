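import numpy as np
import pytest
from hypothesis import settings

from tepflux import build_log_size_classes

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from tepflux.datasets import load_chipie_traps


@pytest.fixture(scope="session")
def grid15():
    """The standard 15 logarithmic classes spanning 1-135 um."""
    return build_log_size_classes(1.0, 135.0, 15)


@pytest.fixture(scope="session")
def chipie():
    """Published minicosm trap table (inputs + published derived cells)."""
    return load_chipie_traps()


@pytest.fixture
def power_law_sample(grid15):
    """Counts constructed so dN/d(dp) = 1000 * dp**-2 exactly at midpoints."""
    from tepflux import TEPSample

    dens = 1000.0 * grid15.midpoints**-2.0
    return TEPSample(counts=dens * grid15.widths, label="exact-power-law")


def brute_force_loglog_slope(x, y):
    """Normal-equations solution for the slope of y = a + b*x in log10 space.

    Independent of numpy.polyfit: builds and solves the 2x2 normal
    equations explicitly.
    """
    lx, ly = np.log10(x), np.log10(y)
    n = lx.size
    sx, sy, sxx, sxy = lx.sum(), ly.sum(), (lx * lx).sum(), (lx * ly).sum()
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)
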