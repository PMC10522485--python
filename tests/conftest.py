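import numpy as np
import pytest

from mhc2x import synthetic


@pytest.fixture
def time_grid():
    return np.linspace(0.0, 240.0, 61)  # minutes


@pytest.fixture
def temp_grid():
    return np.arange(35.0, 95.5, 0.5)  # °C


@pytest.fixture
def receptor_concs():
    # 2-fold dilution series, 4 µM down to ~7.8 nM
    return 4000.0 / 2 ** np.arange(10)


@pytest.fixture
def cpmg_freqs():
    return np.array([50, 100, 150, 200, 250, 300, 400, 500, 600, 700, 800, 950],
                    dtype=float)


@pytest.fixture
def three_state_chain():
    """Reversible 3-state matrix with distinct stationary weights."""
    T = np.array([
        [0.90, 0.07, 0.03],
        [0.14, 0.80, 0.06],
        [0.12, 0.12, 0.76],
    ])
    return T


@pytest.fixture
def feature_trajs(three_state_chain):
    centers = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 3.5]])
    return [synthetic.gen_feature_trajectory(three_state_chain, centers, 0.3, 2,
                                             10000, seed)
            for seed in range(4)]
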