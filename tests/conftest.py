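import numpy as np
import pytest

from scintiresize import PhantomConfig, simulate_view


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down acquisition: 16/32/64 grids on a 64-cell physical field."""
    return PhantomConfig(
        grids=(16, 32, 64),
        pixel_spacing_mm={64: 6.59},
        physical_res=64,
        frame_total_counts=11_000.0,
        n_frames=100,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_series(small_config):
    """A 100-frame 16x16 dynamic series (~11 kcnts/frame)."""
    return simulate_view("ANT", 16, small_config)
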