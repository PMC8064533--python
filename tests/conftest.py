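import math
import warnings

import pytest

from psivol.pipeline import TissueConfig, simulate_tumor
from psivol.stereology import SamplingConfig
from psivol.virtual_tissue import SizeDistribution

MONO_R3 = SizeDistribution("monodisperse", radius=3.0)
MIX_24 = SizeDistribution("two_point", r1=2.0, r2=4.0, weight=0.5)

DENSE_POINTS = SamplingConfig(point_spacing=math.sqrt(10300.84) / 8.0)


@pytest.fixture(scope="session")
def mono_tumor():
    """One monodisperse r=3 µm virtual tumor with raster, reused across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_tumor(MONO_R3, seed=11,
                              tissue=TissueConfig(core_xy=300.0, core_z=20.0))


@pytest.fixture(scope="session")
def small_mono_tumor():
    """A smaller, cheaper tumor for geometry round-trips and CLI tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_tumor(MONO_R3, seed=5,
                              tissue=TissueConfig(core_xy=150.0, core_z=14.0))
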