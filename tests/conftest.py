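import numpy as np
import pytest

from pacemap import simulate as sim

SAR_SITE = (2, 16)
AVC_SITE = (29, 16)


@pytest.fixture(scope="session")
def small_config():
    """32×32 sheet, 3 s, SAR 341 ms vs AVC 600 ms, default noise."""
    return sim.two_pacemaker_config(grid_shape=(32, 32), duration_s=3.0)


@pytest.fixture(scope="session")
def noiseless_config():
    return sim.two_pacemaker_config(
        grid_shape=(32, 32), duration_s=3.0,
        noise_model=sim.NoiseModel(shot_noise_scale=0.0, gaussian_read_sd=0.0))


@pytest.fixture(scope="session")
def small_run(small_config):
    movie, gt = sim.simulate_fret_movie(small_config, seed=11)
    return {"config": small_config, "movie": movie, "gt": gt}


@pytest.fixture(scope="session")
def noiseless_run(noiseless_config):
    movie, gt = sim.simulate_fret_movie(noiseless_config, seed=11)
    voltage = sim.render_voltage(gt, noiseless_config)
    return {"config": noiseless_config, "movie": movie, "gt": gt,
            "voltage": voltage}


@pytest.fixture
def full_mask():
    return np.ones((32, 32), dtype=bool)
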