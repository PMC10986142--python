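import numpy as np
import pytest

from glut4quant.config import PipelineConfig
from glut4quant.synthetic import Condition, EffectSpec


@pytest.fixture
def default_spec() -> EffectSpec:
    return EffectSpec()


@pytest.fixture
def fast_spec() -> EffectSpec:
    """Smaller field and sparser scene for pipeline-level tests."""
    return EffectSpec(
        field_size_um=38.4,
        fibre_radius_um=(9.0, 11.0),
        spot_rates={"PM": 12.0, "L1": 5.0, "L2": 4.0, "L3": 3.0, "L4": 2.0, "L5": 2.0, "interior": 3.0},
    )


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def baseline_condition() -> Condition:
    return Condition("trained", "lipid", 0, "I")


def circle_ring_image(radius=50.0, size=200, centre=None, ring_sigma=1.5, peak=1000.0, offset=50.0):
    """Noiseless dystrophin-like ring raster around a circle."""
    if centre is None:
        centre = (size / 2, size / 2)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    r = np.hypot(rr - centre[0], cc - centre[1])
    return peak * np.exp(-((r - radius) ** 2) / (2 * ring_sigma**2)) + offset


@pytest.fixture
def circle_image():
    return circle_ring_image()
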