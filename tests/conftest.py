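import numpy as np
import pytest

from cfspill import synth


@pytest.fixture(scope="session")
def cf_noiseless():
    """Noiseless climbing-fiber control preset."""
    return synth.preset_with("cf_ctrl", noise_sd=0.0)


@pytest.fixture(scope="session")
def pf_noiseless():
    return synth.preset_with("pf_ctrl", noise_sd=0.0)


@pytest.fixture(scope="session")
def mf_noiseless():
    return synth.preset_with("mf_ctrl", noise_sd=0.0)


@pytest.fixture(scope="session")
def random_trains():
    """100 irregular spike trains for brute-force oracle comparisons."""
    rng = np.random.default_rng(42)
    trials = [
        np.sort(rng.uniform(-500.0, 900.0, rng.integers(0, 15)))
        for _ in range(100)
    ]
    from cfspill.containers import SpikeTrain

    return SpikeTrain(trials, window=(-500.0, 900.0))
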