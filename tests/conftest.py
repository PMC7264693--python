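import warnings

import numpy as np
import pandas as pd
import pytest

from olferp.layout import standard_layout
from olferp.simulate import default_config, generate_behavior

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def layout():
    return standard_layout()


@pytest.fixture(scope="session")
def small_config():
    """Paper-default effect structure at a small participant count."""
    return default_config(n_participants=4, seed=101)


@pytest.fixture(scope="session")
def small_behavior(small_config):
    return generate_behavior(small_config)


def make_recording(layout, data, sfreq=512.0, events=None):
    from olferp.containers import ContinuousRecording

    if events is None:
        events = pd.DataFrame({"sample": [], "label": []})
    return ContinuousRecording(data, sfreq, layout.all_names, events)


@pytest.fixture()
def correlated_background(layout):
    """30 s of spatially smooth multichannel signal (66 x n), ~10 uV rms."""
    rng = np.random.default_rng(7)
    n = int(30 * 512)
    sources = rng.standard_normal((8, n)) * 6.0
    centers = layout.positions[::8][:8]
    weights = np.exp(-((1 - layout.positions @ centers.T) / 0.3))
    data = np.zeros((66, n))
    data[:64] = weights @ sources + rng.standard_normal((64, n)) * 1.0
    data[64:] = rng.standard_normal((2, n)) * 1.0
    return data
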