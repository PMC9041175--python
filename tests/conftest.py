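import numpy as np
import pytest

import minispec as ms
from minispec.simulate import AnalyteSpectrum, SampleModel


@pytest.fixture(scope="session")
def cal():
    return ms.default_calibration()


@pytest.fixture(scope="session")
def instrument():
    return ms.default_instrument()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def flat_analyte():
    # top-hat absorber: epsilon = 1 over 480-620 nm, so A = concentration
    # exactly in the 510-590 nm core (beyond slit-blur reach of the edges)
    return AnalyteSpectrum("flat", flat_bands=((480.0, 620.0, 1.0),))


@pytest.fixture(scope="session")
def flat_sample(flat_analyte):
    return SampleModel(constituents=((flat_analyte, 0.5),))


def make_frame(counts, role="sample", exposure=200.0, bits=10, frame_id="f"):
    return ms.RawSpectrum(
        counts=np.asarray(counts, dtype=np.int64),
        exposure_us=exposure,
        role=role,
        bits=bits,
        frame_id=frame_id,
    )


@pytest.fixture
def frame_factory():
    return make_frame
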