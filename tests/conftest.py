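import numpy as np
import pytest

from tcncall.encoding import WindowSet
from tcncall.simulator import SimulatorConfig, simulate_dataset
from tcncall.tcn import TCNConfig, build_model


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared by training/evaluation tests."""
    cfg = SimulatorConfig(n_refs=2, ref_len=300, n_samples=60, seed=42)
    refs, samples, records, truths = simulate_dataset(cfg)
    return cfg, refs, samples, records, truths


@pytest.fixture()
def tiny_model():
    cfg = TCNConfig(n_channels=8, kernel_size=4, dilations=(1, 2),
                    dropout_rate=0.0, in_dim=17, seed=7)
    return build_model(cfg)


@pytest.fixture()
def random_windows():
    """64 random windows with sparse mutation labels."""
    rng = np.random.default_rng(3)
    ws = WindowSet(60, 10)
    for i in range(64):
        codes = rng.integers(1, 17, size=60)
        labels = np.zeros(60, dtype=np.int64)
        if i % 2:  # half the windows carry mutations
            labels[rng.integers(0, 60, size=2)] = rng.integers(1, 4, size=2)
        ws.items.append((codes, labels, f"w{i}", 0))
    return ws
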