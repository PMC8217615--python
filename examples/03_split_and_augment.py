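"""Partition a crop folder and inspect the load-time augmentation.

The split holds out 33% of each class for testing and 20% of the remainder
for validation (ceiling rounding), the convention that produces the reference
per-class subset sizes shown below; augmentation resizes to 128x128, rotates randomly, flips, and
normalizes.
"""

import numpy as np

from longfission.datasetprep import AugmentSpec, SplitSpec, augment, split_sizes

for n, label in [(2244, "longitudinal division"), (12846, "other division")]:
    train, val, test = split_sizes(n, SplitSpec())
    print(f"{label:>22}: {n:6d} items -> train {train:5d} | val {val:4d} | test {test:4d}")

rng = np.random.default_rng(0)
crop = rng.random((40, 62)).astype(np.float32)  # stand-in for a cell crop
tensor = augment(crop, AugmentSpec(), rng, training=True)
print(f"\naugmented tensor: shape {tensor.shape}, range [{tensor.min():.2f}, {tensor.max():.2f}]")
# Shape (3, 128, 128): grayscale replicated to 3 channels after resize /
# rotation / flips, normalized to roughly [-1, 1] with mean 0.5, std 0.5.
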