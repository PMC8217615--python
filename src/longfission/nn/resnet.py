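"""Width-scalable ResNet-18 built from residual blocks y = x + f(x, w).

Topology: 7x7/2 stem convolution + BN + ReLU + 3x3/2 max pool, four stages of
two basic blocks each (default widths 64/128/256/512, scalable by a width
multiplier for CPU-scale experiments), global average pooling, and a
``num_classes``-way fully connected head.  The first block of stages 2-4
halves resolution and doubles width; its skip path is a 1x1 strided
projection convolution + BN.  When shapes match the skip is the identity, so
driving the inner weights to zero recovers y = x (up to the final ReLU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm2d, Conv2d, GlobalAvgPool, Layer, Linear, MaxPool2d, ReLU


@dataclass(frozen=True)
class NetworkSpec:
    """Stage widths and depths of the classifier; num_classes scores come out."""

    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    num_classes: int = 2
    in_channels: int = 3
    width_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.width_mult <= 0:
            raise ValueError("width multiplier must be > 0")
        if self.num_classes < 1 or any(w < 1 for w in self.stage_widths):
            raise ValueError("invalid widths or class count")

    def scaled_widths(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(w * self.width_mult))) for w in self.stage_widths)


class ResidualBlockSpec:
    """Basic residual block: f = conv3x3-BN-ReLU-conv3x3-BN; output relu(x + f(x)).

    ``stride > 1`` or ``in_ch != out_ch`` switches the skip path to a 1x1
    projection convolution + BN so shapes agree before the addition.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int, *, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        self.projection: list[Layer] | None = None
        if stride != 1 or in_ch != out_ch:
            self.projection = [Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng), BatchNorm2d(out_ch)]

    # -- inner transform f(x, w), exposed so tests can evaluate it alone --
    def inner(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        return self.bn2.forward(h, training)

    def skip(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.projection is None:
            return x
        h = self.projection[0].forward(x, training)
        return self.projection[1].forward(h, training)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.skip(x, training) + self.inner(x, training)
        return self.relu_out.forward(y, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = self.relu_out.backward(dout)
        # inner path
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        # skip path
        if self.projection is None:
            dx = dx + dy
        else:
            ds = self.projection[1].backward(dy)
            dx = dx + self.projection[0].backward(ds)
        return dx

    def named_layers(self) -> list[tuple[str, Layer]]:
        out = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.projection is not None:
            out += [("downsample.0", self.projection[0]), ("downsample.1", self.projection[1])]
        return out


def residual_block_forward(x: np.ndarray, block: ResidualBlockSpec, training: bool = False) -> np.ndarray:
    """Evaluate one residual block: relu(x + f(x, w)) (projection skip if shapes change)."""
    return block.forward(x, training)


class ResNet:
    """The assembled network; see :class:`NetworkSpec` for the topology knobs."""

    def __init__(self, spec: NetworkSpec, *, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        widths = spec.scaled_widths()
        self.stem_conv = Conv2d(spec.in_channels, widths[0], 7, stride=2, pad=3, rng=rng, input_grad=False)
        self.stem_bn = BatchNorm2d(widths[0])
        self.stem_relu = ReLU()
        self.pool = MaxPool2d(3, 2, 1)
        self.blocks: list[ResidualBlockSpec] = []
        in_ch = widths[0]
        for stage, (w, nblocks) in enumerate(zip(widths, spec.blocks_per_stage)):
            for b in range(nblocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(ResidualBlockSpec(in_ch, w, stride, rng=rng))
                in_ch = w
        self.gap = GlobalAvgPool()
        self.fc = Linear(in_ch, spec.num_classes, rng=rng)

    # ---------------- forward / backward ----------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.stem_conv.forward(x.astype(np.float32, copy=False), training)
        h = self.stem_bn.forward(h, training)
        h = self.stem_relu.forward(h, training)
        h = self.pool.forward(h, training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        h = self.gap.forward(h, training)
        return self.fc.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.gap.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        d = self.pool.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem_conv.backward(d)

    # ---------------- parameter plumbing ----------------

    def named_layers(self) -> list[tuple[str, Layer]]:
        out = [("conv1", self.stem_conv), ("bn1", self.stem_bn)]
        per_stage = self.spec.blocks_per_stage
        i = 0
        for stage, nblocks in enumerate(per_stage, start=1):
            for b in range(nblocks):
                for name, layer in self.blocks[i].named_layers():
                    out.append((f"layer{stage}.{b}.{name}", layer))
                i += 1
        out.append(("fc", self.fc))
        return out

    def parameters(self) -> list[np.ndarray]:
        return [p for _, layer in self.named_layers() for p in layer.params.values()]

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[k] for _, layer in self.named_layers() for k in layer.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for prefix, layer in self.named_layers():
            for k, v in layer.params.items():
                out[f"{prefix}.{k}"] = v.copy()
            for k, v in layer.buffers.items():
                out[f"{prefix}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {f"{prefix}.{k}": (layer, k, True) for prefix, layer in self.named_layers() for k in layer.params}
        own.update(
            {f"{prefix}.{k}": (layer, k, False) for prefix, layer in self.named_layers() for k in layer.buffers}
        )
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch; missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, arr in state.items():
            layer, key, is_param = own[name]
            target = layer.params if is_param else layer.buffers
            if target[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {target[key].shape} vs {arr.shape}")
            target[key] = np.asarray(arr, dtype=np.float32).copy()


def build_network(spec: NetworkSpec, *, rng: np.random.Generator | None = None) -> ResNet:
    """Construct the classifier; all weights drawn from ``rng``."""
    return ResNet(spec, rng=rng)


def save_checkpoint(network: ResNet, path) -> None:
    np.savez(path, **network.state_dict())


def load_checkpoint(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def load_pretrained(network: ResNet, checkpoint, num_classes: int | None = None) -> ResNet:
    """Initialize every layer except the head from a checkpoint (transfer learning).

    ``checkpoint`` is a path or a state dict.  The fully connected head is
    re-initialized to zero for the target class count (it may differ from the
    checkpoint's): with a zero head the first updates train the head alone —
    the gradient reaching the body through a zero weight matrix is zero — so
    the transferred features are not disturbed before the head aligns.  All
    layers remain trainable throughout.  A topology mismatch raises an error
    listing the incompatible entries.
    """
    state = checkpoint if isinstance(checkpoint, dict) else load_checkpoint(checkpoint)
    if num_classes is not None and num_classes != network.spec.num_classes:
        raise ValueError("network head does not have the requested class count")
    own = network.state_dict()
    body_keys = [k for k in own if not k.startswith("fc.")]
    bad = [k for k in body_keys if k not in state or state[k].shape != own[k].shape]
    missing = [k for k in body_keys if k not in state]
    if bad:
        raise ValueError(f"incompatible checkpoint layers: {sorted(set(bad + missing))}")
    merged = {k: (state[k] if k in body_keys else np.zeros_like(own[k])) for k in own}
    network.load_state_dict(merged)
    return network
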