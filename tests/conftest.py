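import numpy as np
import pytest

from fallcnn.signal_io import AccelTrace, LabeledDataset, Window
from fallcnn.synthetic_data import SimConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trace(rng):
    """A 100-sample trace with distinguishable per-channel ranges."""
    xyz = np.column_stack([
        rng.uniform(-2, 2, 100),
        rng.uniform(0, 1, 100),
        rng.uniform(-10, 10, 100),
    ])
    return AccelTrace(np.arange(100), xyz, source_id="unit")


@pytest.fixture
def tiny_dataset():
    """6 fall + 8 ADL windows of length 25, deterministic."""
    return gen_dataset(SimConfig(window_length=25, seed=7), 6, 8)


@pytest.fixture
def labeled_windows(rng):
    """10 labeled random windows (L=12), 4 fall / 6 adl."""
    windows = []
    for i in range(10):
        label = "fall" if i < 4 else "adl"
        windows.append(Window(rng.normal(size=(12, 3)), label=label,
                              origin=f"w{i}"))
    return LabeledDataset(windows)
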