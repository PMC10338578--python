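import numpy as np
import pytest

from hemocoupling import BoldSeries, PipelineConfig
from hemocoupling.simulate import BandLimitedSignal, SimSpec, simulate_subject


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def make_bold(series: np.ndarray, tr: float = 2.3) -> BoldSeries:
    """Wrap a (V, T) matrix as a 1-D-in-space BoldSeries (V x 1 x 1 grid)."""
    v, t = series.shape
    data = series.reshape(v, 1, 1, t).astype(float)
    return BoldSeries(data=data, tr=tr, affine=np.eye(4),
                      mask=np.ones((v, 1, 1), bool))


@pytest.fixture
def band_signal(rng):
    return BandLimitedSignal(rng, (0.012, 0.078), 40)


@pytest.fixture(scope="session")
def compact_subject():
    """One deterministic compact synthetic subject, shared across tests."""
    spec = SimSpec.compact(seed=7)
    return spec, simulate_subject(spec, seed=7)
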