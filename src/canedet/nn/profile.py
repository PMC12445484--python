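"""Complexity accounting: exact parameter totals and per-forward MACs.

``profile_macs`` runs one forward pass in shape-only mode: convolutions
count their multiply-accumulates and emit zeros without doing the
arithmetic, so profiling a 640-pixel input is immediate.  GFLOPs follow
the MACs-times-two convention that detector complexity tables use
(normalizations, activations, pooling and resizing count as zero).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, no_grad
from .modules import PROFILER

__all__ = ["count_parameters", "profile_macs", "gflops"]


def count_parameters(net, fused: bool = True) -> int:
    return net.param_count(fused=fused)


def profile_macs(net, input_shape=(1, 3, 640, 640), shape_only: bool = True) -> int:
    """Multiply-accumulates of one forward pass at the given input shape."""
    was_training = getattr(net, "training", True)
    net.eval()
    PROFILER.reset()
    PROFILER.active = True
    PROFILER.shape_only = shape_only
    try:
        with no_grad():
            net(Tensor(np.zeros(input_shape, dtype=np.float32)))
    finally:
        PROFILER.active = False
        PROFILER.shape_only = False
        net.train(was_training)
    return PROFILER.macs


def gflops(net, input_size: int = 640) -> float:
    """GFLOPs at a square input, MACs x 2 / 1e9."""
    return 2.0 * profile_macs(net, (1, 3, input_size, input_size)) / 1e9
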