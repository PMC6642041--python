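import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained network with dropout, for shape/sampling contracts."""
    from histonet.network import HistoNet, NetConfig

    cfg = NetConfig(
        levels=2,
        base_width=8,
        bottleneck_factor=2,
        blocks_per_level=1,
        compression_widths=(4, 6),
        dropout_rate=0.1,
        seed=7,
    )
    return HistoNet(cfg)


@pytest.fixture(scope="session")
def tiny_model_nodrop():
    from histonet.network import HistoNet, NetConfig

    cfg = NetConfig(
        levels=2,
        base_width=8,
        bottleneck_factor=2,
        blocks_per_level=1,
        compression_widths=(4, 6),
        dropout_rate=0.0,
        seed=7,
    )
    return HistoNet(cfg)
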