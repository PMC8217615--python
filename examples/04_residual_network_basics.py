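"""Convolution and residual-block semantics on paper-sized examples.

Shows the classic 4x4-image / 2x2-kernel worked example (a 3x3 feature map
of inner products) and the defining property of a residual block: with its
inner weights at zero the block is the identity map.
"""

import numpy as np

from longfission.nn import ConvSpec, ResidualBlockSpec, convolve2d_valid, residual_block_forward

image = np.array([[0, 1, 0, 1], [0, 1, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=float)
a, b, c, d = 1.0, 2.0, 3.0, 4.0
fmap = convolve2d_valid(image, ConvSpec(np.array([[a, b], [c, d]]), stride=1))
print("feature map (3x3):")
print(fmap)
print(f"top-left = b+d = {fmap[0, 0]:.0f}; next = a+c+d = {fmap[0, 1]:.0f}; then b+c = {fmap[0, 2]:.0f}")

block = ResidualBlockSpec(4, 4, stride=1, rng=np.random.default_rng(0))
block.conv1.params["weight"][:] = 0.0
block.conv2.params["weight"][:] = 0.0
x = np.random.default_rng(1).random((1, 4, 8, 8)).astype(np.float32)
y = residual_block_forward(x, block)
print(f"\nzero-weight residual block: max |y - x| = {np.abs(y - x).max():.2e}")
# The skip connection carries x through unchanged: y = x + f(x, w) with f = 0,
# which is why residual networks stay trainable at depth.
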