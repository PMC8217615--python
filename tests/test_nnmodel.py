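"""Convolution semantics, residual blocks, topology, and weight transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_conv
from longfission.nn import (
    ConvSpec,
    NetworkSpec,
    ResidualBlockSpec,
    build_network,
    convolve2d_valid,
    load_pretrained,
    residual_block_forward,
    save_checkpoint,
)

# The 4x4 binary image swept by a 2x2 kernel (a,b,c,d) in the classic worked
# example: the first receptive fields respond b+d, a+c+d, b+c, then b+d again.
WORKED_IMAGE = np.array(
    [
        [0, 1, 0, 1],
        [0, 1, 1, 0],
        [0, 1, 0, 1],
        [1, 0, 1, 0],
    ],
    dtype=float,
)


class TestConvolve2dValid:
    def test_worked_example_shape_and_symbolic_responses(self):
        a, b, c, d = 1.0, 2.0, 3.0, 4.0
        kernel = np.array([[a, b], [c, d]])
        fmap = convolve2d_valid(WORKED_IMAGE, ConvSpec(kernel))
        assert fmap.shape == (3, 3)  # 4x4 image, 2x2 kernel, stride 1
        assert fmap[0, 0] == b + d
        assert fmap[0, 1] == a + c + d
        assert fmap[0, 2] == b + c
        assert fmap[1, 0] == b + d
        # the whole map must agree with the nested-loop oracle
        assert np.array_equal(fmap, brute_conv(WORKED_IMAGE, kernel))

    def test_symbolic_identities_hold_for_second_instantiation(self):
        # a different weight instantiation distinguishes b+d from a+c etc.
        a, b, c, d = 10.0, 1.0, 100.0, 7.0
        fmap = convolve2d_valid(WORKED_IMAGE, ConvSpec(np.array([[a, b], [c, d]])))
        assert fmap[0, 0] == b + d and fmap[0, 1] == a + c + d and fmap[0, 2] == b + c

    def test_identity_kernel_returns_input(self, rng):
        img = rng.random((6, 7))
        assert np.array_equal(convolve2d_valid(img, ConvSpec(np.ones((1, 1)))), img)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 2))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_brute_force_on_integer_images(self, seed, stride):
        r = np.random.default_rng(seed)
        img = r.integers(-5, 6, (8, 8)).astype(float)
        kernel = r.integers(-3, 4, (3, 3)).astype(float)
        fast = convolve2d_valid(img, ConvSpec(kernel, stride=stride))
        assert np.array_equal(fast, brute_conv(img, kernel, stride))

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            convolve2d_valid(np.zeros((2, 2)), ConvSpec(np.ones((3, 3))))

    def test_multichannel_sums_over_channels(self, rng):
        img = rng.random((2, 5, 5))
        k = rng.random((2, 3, 3))
        out = convolve2d_valid(img, ConvSpec(k))
        expected = brute_conv(img[0], k[0]) + brute_conv(img[1], k[1])
        assert np.allclose(out, expected)


class TestResidualBlock:
    def _zero_block(self, ch=4):
        block = ResidualBlockSpec(ch, ch, 1, rng=np.random.default_rng(0))
        block.conv1.params["weight"][:] = 0
        block.conv2.params["weight"][:] = 0
        return block

    def test_zero_weights_give_identity(self, rng):
        # driving w to zero establishes y = x (non-negative activations)
        block = self._zero_block()
        x = rng.random((2, 4, 8, 8)).astype(np.float32)
        assert np.allclose(residual_block_forward(x, block), x, atol=1e-6)

    def test_constant_inner_map_adds_elementwise(self, rng):
        block = self._zero_block()
        block.bn2.params["bias"][:] = 0.7  # f(x) == 0.7 everywhere
        x = rng.random((1, 4, 6, 6)).astype(np.float32)
        pre = block.skip(x, False) + block.inner(x, False)
        assert np.allclose(pre, x + 0.7, atol=1e-6)

    def test_output_minus_skip_equals_inner_path(self, rng):
        block = ResidualBlockSpec(3, 3, 1, rng=rng)
        x = (rng.random((2, 3, 8, 8)) + 0.5).astype(np.float32)
        out = residual_block_forward(x, block)
        f = block.inner(x, False)
        assert np.allclose(out, np.maximum(x + f, 0.0), atol=1e-5)

    def test_projection_skip_changes_shape(self, rng):
        block = ResidualBlockSpec(4, 8, 2, rng=rng)
        out = residual_block_forward(rng.random((1, 4, 8, 8)).astype(np.float32), block)
        assert out.shape == (1, 8, 4, 4)


class TestBuildNetwork:
    def test_head_outputs_two_scores(self, rng):
        net = build_network(NetworkSpec(width_mult=0.125), rng=rng)
        out = net.forward(rng.random((1, 3, 128, 128)).astype(np.float32))
        assert out.shape == (1, 2)
        assert np.isfinite(out).all()

    def test_parameter_count_monotone_in_width(self):
        def count(mult):
            net = build_network(NetworkSpec(width_mult=mult), rng=np.random.default_rng(0))
            return sum(p.size for p in net.parameters())

        assert count(0.25) < count(1.0)

    def test_zero_weight_network_is_identity_up_to_head(self, rng):
        net = build_network(NetworkSpec(width_mult=0.125), rng=rng)
        for _, layer in net.named_layers():
            if "weight" in layer.params and layer.params["weight"].ndim == 4:
                layer.params["weight"][:] = 0
        net.fc.params["bias"][:] = np.array([0.3, -0.2], dtype=np.float32)
        out = net.forward(rng.random((2, 3, 64, 64)).astype(np.float32))
        assert np.allclose(out, [0.3, -0.2], atol=1e-6)

    def test_forward_deterministic(self, rng):
        net = build_network(NetworkSpec(width_mult=0.125), rng=np.random.default_rng(1))
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(width_mult=0.0)


class TestLoadPretrained:
    def test_body_roundtrips_head_reinitialized(self, tmp_path, rng):
        donor = build_network(NetworkSpec(width_mult=0.125, num_classes=5), rng=np.random.default_rng(1))
        ckpt = tmp_path / "donor.npz"
        save_checkpoint(donor, ckpt)
        target = build_network(NetworkSpec(width_mult=0.125, num_classes=2), rng=np.random.default_rng(2))
        load_pretrained(target, ckpt)
        donor_state = donor.state_dict()
        for key, val in target.state_dict().items():
            if key.startswith("fc."):
                # zero head: first updates cannot disturb the transferred body
                assert not val.any()
            else:
                assert np.array_equal(val, donor_state[key])
        out = target.forward(rng.random((1, 3, 64, 64)).astype(np.float32))
        assert out.shape == (1, 2)
        assert np.allclose(out, 0.0)

    def test_topology_mismatch_lists_incompatible_layers(self, tmp_path):
        donor = build_network(NetworkSpec(width_mult=0.25), rng=np.random.default_rng(0))
        ckpt = tmp_path / "donor.npz"
        save_checkpoint(donor, ckpt)
        target = build_network(NetworkSpec(width_mult=0.125), rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="conv1"):
            load_pretrained(target, ckpt)
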