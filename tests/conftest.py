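import numpy as np
import pandas as pd
import pytest

from nodeloc import (
    GUAM_DECAY_MODEL,
    LocalizationInput,
    NetworkConfig,
    NodeSignal,
    make_network,
)


@pytest.fixture(scope="session")
def model():
    """The published field-calibrated decay curve used throughout."""
    return GUAM_DECAY_MODEL


@pytest.fixture(scope="session")
def grid100():
    return make_network(NetworkConfig(layout="uniform", spacing_m=100.0, extent_m=1250.0))


@pytest.fixture(scope="session")
def grid250():
    return make_network(NetworkConfig(layout="uniform", spacing_m=250.0, extent_m=1250.0))


def make_input(signals: dict[str, float], counts: dict[str, int] | None = None):
    """Build a LocalizationInput from {node_id: mean_rss}."""
    counts = counts or {}
    return LocalizationInput(
        tag_id="tag",
        window_start=pd.Timestamp("2021-01-01T00:00:00Z"),
        window_end=pd.Timestamp("2021-01-01T00:01:00Z"),
        signals={n: NodeSignal(r, counts.get(n, 1)) for n, r in signals.items()},
    )


def noise_free_input(network, model, location):
    """Per-node RSS exactly on the decay curve for a known location."""
    d = np.hypot(network.xy[:, 0] - location[0], network.xy[:, 1] - location[1])
    rss = model.a * np.exp(-model.S * d) + model.K
    return make_input({str(n): float(r) for n, r in zip(network.ids, rss)})
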