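import numpy as np
import pytest

from spermqpi.phantom import PhantomParams, generate_dataset, generate_phantom
from spermqpi.types import CarrierSpec, NoiseModel


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Reduced field for classification-scale tests: 192 px at 0.2 µm/px."""
    return PhantomParams(
        image_height_px=192, image_width_px=192, pixel_pitch=0.2, tail_length=25.0
    )


@pytest.fixture(scope="session")
def ideal_noise() -> NoiseModel:
    """Noise-free instrument with an unquantized detector."""
    return NoiseModel(regime="none", bit_depth=0)


@pytest.fixture(scope="session")
def default_phantom(default_params):
    return generate_phantom(default_params, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """20 labelled maps (5 per class) at full effect size."""
    return generate_dataset(5, small_params, effect_size=1.0, seed=11)


@pytest.fixture(scope="session")
def qc_dataset(default_params):
    """8 labelled maps (2 per class) at instrument geometry (512 px, 0.108 µm/px)."""
    return generate_dataset(2, default_params, effect_size=0.5, seed=19)


def wrapped_of(values: np.ndarray, pixel_pitch: float = 0.108):
    from spermqpi.types import WrappedPhase
    from spermqpi.unwrap import wrap

    return WrappedPhase(values=wrap(values), pixel_pitch=pixel_pitch)
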