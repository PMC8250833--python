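import numpy as np
import pytest

from sandflux.profiles import Analyte, DepthProfile, ProfileSeries, SedimentCore


@pytest.fixture
def core() -> SedimentCore:
    return SedimentCore()


@pytest.fixture
def depth_grid() -> np.ndarray:
    return np.arange(0.0, 0.040001, 0.001)


def make_series(analyte, depths, times, conc, core_id="test"):
    """Build a ProfileSeries from an (n_times, n_depths) array."""
    conc = np.asarray(conc, dtype=float)
    profiles = [DepthProfile(analyte=analyte, depths=np.asarray(depths, float),
                             concentrations=conc[i], time_h=float(t))
                for i, t in enumerate(times)]
    return ProfileSeries(profiles=profiles, core_id=core_id)


@pytest.fixture
def small_n2o_series(depth_grid):
    """Spatially uniform linear N2O accumulation, C = 2t."""
    times = np.array([0.0, 0.5, 1.0, 1.5])
    conc = np.array([[2.0 * t] * depth_grid.size for t in times])
    return make_series(Analyte.N2O, depth_grid, times, conc)
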