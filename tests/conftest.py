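import numpy as np
import pytest

import camon


@pytest.fixture(scope="session")
def small_stft_cfg():
    """Fast Welch geometry (20.48 s frames) for unit tests."""
    # band widened to match the coarser 0.195 Hz bin spacing of short windows
    return camon.StftConfig(n_frame=2048, n_win=512, n_shift=128, dt=0.01,
                            band=(0.1, 5.0))


@pytest.fixture(scope="session")
def small_cwt_cfg():
    return camon.CwtConfig(n_frame=2048, n_shift=256, dt=0.01)


@pytest.fixture(scope="session")
def mayer_only_components():
    """Single shared 0.1 Hz component, unit-free baselines."""
    return (camon.Component("mayer", 0.10, 2.0, 4.0),)


@pytest.fixture(scope="session")
def coherent_pair(mayer_only_components):
    """Noise-free pair with a constant +1 rad Mayer phase shift."""
    spec = camon.SimulationSpec(
        duration=250.0,
        noise_sd_bp=0.0,
        noise_sd_bfv=0.0,
        theta=camon.ThetaProfile(1.0),
        seed=0,
    )
    return camon.simulate_pair(spec)


@pytest.fixture(scope="session")
def noisy_pair():
    """Default-SNR pair, 250 s, constant healthy baseline phase shift."""
    return camon.simulate_pair(camon.SimulationSpec(duration=250.0, seed=7))
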