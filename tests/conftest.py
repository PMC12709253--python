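import numpy as np
import pytest

from axobeat import SyntheticBeatParams, generate_tangent_field
from axobeat.preprocess import segment_beats


@pytest.fixture(scope="session")
def unit_ratio_params():
    """Standard beat with wavelength equal to length (L = λ0 = 10 μm)."""
    return SyntheticBeatParams(
        length_um=10.0, wavelength_um=10.0, amplitude_rad=0.5, frequency_hz=65.0
    )


@pytest.fixture(scope="session")
def unit_ratio_field(unit_ratio_params):
    return generate_tangent_field(unit_ratio_params)


@pytest.fixture(scope="session")
def unit_ratio_segmentation(unit_ratio_field, unit_ratio_params):
    return segment_beats(unit_ratio_field, unit_ratio_params.frequency_hz)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
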