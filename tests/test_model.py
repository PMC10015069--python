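"""Architecture contracts: front-end resolution, SE attention oracle,
ablation configurations, non-negativity and statelessness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from swarmcount import (ModelConfig, MosquitoCounter, SEModule, build_amrn,
                        build_fen, fen_output_shape)


def floor_halvings(n, times):
    for _ in range(times):
        n //= 2
    return n


class TestShapes:
    def test_default_fen_is_one_eighth(self):
        """10-conv front end: 512 channels at three floor-halvings."""
        fen = build_fen(ModelConfig(), seed=0)
        x = np.random.default_rng(0).random((1, 3, 48, 40))
        y = fen.forward(x)
        assert y.shape == (1, 512, 6, 5)

    def test_13_layer_fen_is_one_thirtysecond(self):
        fen = build_fen(ModelConfig(fen_layers=13), seed=0)
        x = np.random.default_rng(0).random((1, 3, 160, 128))
        y = fen.forward(x)
        assert y.shape == (1, 512, 5, 4)

    def test_dataset_frame_output_shape(self):
        """A 960x540 frame maps to a 120x67 grid under three halvings."""
        assert fen_output_shape((540, 960), fen_layers=10) == (67, 120)

    @given(h=st.integers(16, 72), w=st.integers(16, 72))
    def test_output_equals_floor_halvings_for_any_size(self, h, w, tiny_model):
        x = np.random.default_rng(1).random((1, 3, h, w))
        y = tiny_model.forward_tensor(x)
        assert y.shape[2:] == (floor_halvings(h, 2), floor_halvings(w, 2))

    def test_input_below_minimum_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="minimum"):
            tiny_model.forward_tensor(np.zeros((1, 3, 8, 8)))

    def test_wrong_channel_count_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward_tensor(np.zeros((1, 1, 32, 32)))


class TestDefaultArchitecture:
    def test_three_branches_with_se_only_on_7x7(self):
        head = build_amrn(ModelConfig(), in_channels=8, seed=0)
        kernels = [b.kernel for b in head.branches]
        assert kernels == [3, 5, 7]
        assert [b.has_se for b in head.branches] == [False, False, True]

    def test_branch_channels_strictly_decrease(self):
        with pytest.raises(ValueError, match="decrease"):
            ModelConfig(branch_channels=(64, 64, 32))

    def test_head_preserves_spatial_dims_and_outputs_one_channel(self):
        head = build_amrn(ModelConfig(branch_channels=(6, 5, 4)),
                          in_channels=4, seed=0)
        y = head.forward(np.random.default_rng(0).random((2, 4, 9, 13)))
        assert y.shape == (2, 1, 9, 13)


class TestAblationConfigs:
    """Every ablation cell (front-end depth, single vs multi scale, SE
    placement) must be a constructible configuration."""

    @pytest.mark.parametrize("layers,scale", [(7, 4), (10, 8), (13, 32)])
    def test_fen_depths(self, layers, scale):
        cfg = ModelConfig(fen_layers=layers)
        assert cfg.fen_scale == scale

    def test_single_scale_variant(self):
        cfg = ModelConfig(branch_kernels=(7,), se_branches=frozenset({7}))
        assert cfg.branch_kernels == (7,)

    @pytest.mark.parametrize("se", [frozenset(), frozenset({3}), frozenset({5}),
                                    frozenset({7}), frozenset({3, 5, 7})])
    def test_se_placements(self, se):
        cfg = ModelConfig(se_branches=se)
        head = build_amrn(cfg, in_channels=4, seed=0)
        assert {b.kernel for b in head.branches if b.has_se} == set(se)

    def test_se_on_missing_branch_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ModelConfig(branch_kernels=(3, 5), se_branches=frozenset({7}))

    def test_unsupported_depth_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(fen_layers=11)


class TestSEModule:
    def se_oracle(self, se, x):
        """Straight-line recomputation: explicit mean, two matrix products,
        sigmoid, broadcast multiply."""
        n, c, h, w = x.shape
        z = x.reshape(n, c, h * w).mean(axis=2)
        a = z @ se.fc1.weight.value.T + se.fc1.bias.value
        a = np.maximum(a, 0)
        a = a @ se.fc2.weight.value.T + se.fc2.bias.value
        gates = 1 / (1 + np.exp(-a))
        return x * gates[:, :, None, None], gates

    def test_squeeze_of_constant_channel_is_its_value(self, rng):
        se = SEModule(3, reduction=1, rng=rng)
        x = np.zeros((1, 3, 4, 4))
        x[0, 1] = 2.5
        assert np.allclose(se.squeeze.forward(x), [[0.0, 2.5, 0.0]])

    def test_matches_straight_line_oracle(self, rng):
        se = SEModule(6, reduction=2, rng=rng)
        x = rng.normal(size=(3, 6, 5, 7))
        y = se.forward(x)
        expect, gates = self.se_oracle(se, x)
        assert np.abs(y - expect).max() < 1e-6
        assert ((gates > 0) & (gates < 1)).all()

    def test_identity_when_gates_forced_open(self, rng):
        se = SEModule(4, reduction=2, rng=rng)
        se.fc2.weight.value[:] = 0.0
        se.fc2.bias.value[:] = 60.0  # sigmoid saturates to 1
        x = rng.normal(size=(2, 4, 3, 3))
        assert np.allclose(se.forward(x), x)

    def test_gating_never_amplifies(self, rng):
        se = SEModule(5, reduction=2, rng=rng)
        x = rng.normal(size=(2, 5, 4, 4))
        y = se.forward(x)
        assert (np.abs(y) <= np.abs(x) + 1e-12).all()

    def test_nonpositive_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            SEModule(4, reduction=0, rng=rng)


class TestForward:
    def test_zero_image_with_zero_bias_gives_zero_mass(self, tiny_config):
        model = MosquitoCounter(tiny_config, seed=0)
        model.head.fuse.bias.value[:] = 0.0
        d = model.predict_density(np.zeros((40, 40, 3), dtype=np.uint8))
        assert d.mass == 0.0

    def test_nonnegative_density_for_random_inputs(self, tiny_model, rng):
        for _ in range(3):
            img = rng.integers(0, 256, size=(36, 52, 3), dtype=np.uint8)
            d = tiny_model.predict_density(img)
            assert (d.values >= 0).all()
            assert d.scale == tiny_model.scale

    def test_batch_statelessness(self, tiny_model, rng):
        a = rng.random((1, 3, 32, 32))
        b = rng.random((1, 3, 32, 32))
        batched = tiny_model.forward_tensor(np.concatenate([a, b]))
        alone = tiny_model.forward_tensor(a)
        assert np.allclose(batched[0], alone[0], atol=1e-12)

    def test_forward_is_deterministic(self, tiny_model, rng):
        img = rng.integers(0, 256, size=(40, 48, 3), dtype=np.uint8)
        d1 = tiny_model.predict_density(img)
        d2 = tiny_model.predict_density(img)
        assert np.array_equal(d1.values, d2.values)


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, tiny_config, tmp_path, rng):
        model = MosquitoCounter(tiny_config, seed=1)
        img = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
        before = model.predict_density(img).values
        path = model.save_weights(tmp_path / "ckpt.npz")
        other = MosquitoCounter.from_checkpoint(path)
        assert np.array_equal(other.predict_density(img).values, before)

    def test_pretrained_without_weights_file_fails(self):
        with pytest.raises(ValueError, match="weights"):
            build_fen(ModelConfig(), pretrained=True)
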