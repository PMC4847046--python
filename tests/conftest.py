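import numpy as np
import pytest

from krigfuse.types import Analyte, Instrument, Role, SamplePoint, SampleSet


def make_samples(coords, values, instrument=Instrument.PRIMARY,
                 analyte=Analyte.CU, prefix="p", log_transformed=False,
                 role=Role.TRAIN):
    pts = [
        SamplePoint(f"{prefix}{i}", float(x), float(y), float(v),
                    instrument, analyte, role)
        for i, ((x, y), v) in enumerate(zip(coords, values))
    ]
    return SampleSet(pts, analyte, log_transformed)


def random_samples(rng, n, extent=100.0, lo=1.0, hi=10.0, **kw):
    coords = rng.uniform(0, extent, size=(n, 2))
    values = rng.uniform(lo, hi, size=n)
    return make_samples(coords, values, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def samples_factory():
    return make_samples


@pytest.fixture
def random_samples_factory():
    return random_samples
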