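"""Parameter and multiply-accumulate accounting.

The MAC convention counts convolution and linear layers only (kernel-area x
in-channels x out-channels x output-positions for convolutions, in x out x
token-count for linear maps); attention score/value matrix products,
normalisation and elementwise operations are excluded.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, no_grad
from .layers import Module, profiling_scope

__all__ = ["count_parameters", "count_macs", "format_gmac"]


def count_parameters(model: Module) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.size for p in model.parameters()))


def count_macs(model: Module, input_shape: tuple[int, int, int]) -> int:
    """Multiply-accumulates for one forward pass on a single input.

    ``input_shape`` is (channels, height, width).
    """
    c, h, w = input_shape
    x = Tensor(np.zeros((1, c, h, w), dtype=np.float32))
    counter: dict[str, int] = {}
    was_training = model.training
    model.eval()
    try:
        with no_grad(), profiling_scope(counter):
            model(x)
    finally:
        model.train(was_training)
    return int(sum(counter.values()))


def format_gmac(macs: int) -> str:
    """Format an absolute MAC count as GMAC with two decimals."""
    return f"{macs / 1e9:.2f}"
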