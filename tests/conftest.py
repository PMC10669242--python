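import numpy as np
import pytest

from rckd.csat import CSATConfig


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature CSAT: same topology as the full network, desk-scale widths."""
    return CSATConfig(stem_channels=8, stem_hidden=8, stage_depths=[1, 1, 1, 1],
                      stage_transformers=[0, 0, 1, 1], stage_channels=[8, 12, 16, 24],
                      pooled_size=4, transformer_heads=4, num_classes=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
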