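"""Contract tests for the segmenter, attention blocks, refine network,
parameter partition, and checkpointing."""

import numpy as np
import pytest

from wavtta.models import (
    ConfigurationError,
    NetworkConfig,
    RefineNetConfig,
    SubbandAttention,
    build_refine_model,
    build_wavnet,
    load_checkpoint,
    partition_parameters,
    save_checkpoint,
    subband_attention,
)
from wavtta.nn import Tensor


@pytest.fixture()
def tiny_model(tiny_config, db2):
    return build_wavnet(tiny_config, db2)


@pytest.fixture()
def tiny_volume(rng):
    return rng.random((16, 16, 16))


class TestConfig:
    def test_channel_stage_mismatch(self):
        with pytest.raises(ConfigurationError, match="encoder_channels"):
            NetworkConfig(stages=5, encoder_channels=(4, 8)).validate()

    def test_resolution_divisibility(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            NetworkConfig(
                stages=5, encoder_channels=(2,) * 5, base_resolution=(24, 24, 24)
            ).validate()

    def test_multiclass_rejected(self):
        with pytest.raises(ConfigurationError, match="binary"):
            NetworkConfig(num_classes=3).validate()


class TestWaVNet:
    def test_output_shape_and_range_full_model(self, db2, rng):
        # paper-profile 5-stage model on a 64^3 input
        model = build_wavnet(NetworkConfig(base_resolution=(64, 64, 64)), db2)
        out = model.predict(rng.random((64, 64, 64)))
        assert out.shape == (64, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_eval_determinism_bitwise(self, tiny_model, tiny_volume):
        a = tiny_model.predict(tiny_volume)
        b = tiny_model.predict(tiny_volume)
        assert np.array_equal(a, b)

    def test_seeded_construction_reproducible(self, tiny_config, db2):
        a = build_wavnet(tiny_config, db2)
        b = build_wavnet(tiny_config, db2)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)

    def test_forced_zero_sa_equals_zeroed_wavelet_channels(self, tiny_model, tiny_volume):
        for block in tiny_model.sa_blocks:
            block.force_weights = np.zeros(8)
        try:
            forced = tiny_model.predict(tiny_volume)
        finally:
            for block in tiny_model.sa_blocks:
                block.force_weights = None
        with_zeroed = tiny_model.eval()
        from wavtta.nn import no_grad

        with no_grad():
            zeroed = tiny_model.forward(tiny_volume, zero_wavelet=True).data[0]
        assert np.array_equal(forced, zeroed)

    def test_indivisible_input_rejected(self, tiny_model, rng):
        with pytest.raises(ConfigurationError, match="divisible"):
            tiny_model.forward(rng.random((12, 16, 16)))

    def test_sa_weights_recorded_per_level(self, tiny_model, tiny_volume):
        tiny_model.predict(tiny_volume)
        weights = tiny_model.sa_weights()
        assert set(weights) == {1, 2, 3}
        for w in weights.values():
            assert w.shape == (8,)
            assert np.all((w > 0) & (w < 1))

    def test_plain_vnet_without_wavelet(self, db2, rng):
        config = NetworkConfig(
            stages=4, encoder_channels=(2, 4, 4, 4), base_resolution=(16, 16, 16),
            use_wavelet=False,
        )
        model = build_wavnet(config, db2)
        out = model.predict(rng.random((16, 16, 16)))
        assert out.shape == (16, 16, 16)
        assert len(model.sa_blocks) == 0


class TestSubbandAttention:
    def test_forced_half_weights_halve_bands(self, rng):
        block = SubbandAttention(8, 2, rng)
        block.force_weights = np.full(8, 0.5)
        bands = rng.normal(size=(8, 4, 4, 4))
        weighted, weights = subband_attention(bands, block)
        assert np.allclose(weighted.data, bands * 0.5)
        assert np.allclose(weights.data, 0.5)

    def test_zero_bands_stay_zero(self, rng):
        block = SubbandAttention(8, 2, rng)
        weighted, _ = subband_attention(np.zeros((8, 4, 4, 4)), block)
        assert np.all(weighted.data == 0)

    def test_weights_in_unit_interval(self, rng):
        block = SubbandAttention(8, 2, rng)
        _, weights = subband_attention(rng.normal(size=(8, 4, 4, 4)), block)
        assert np.all((weights.data > 0) & (weights.data < 1))

    def test_band_count_mismatch(self, rng):
        block = SubbandAttention(8, 2, rng)
        with pytest.raises(ValueError, match="8 sub-band"):
            subband_attention(np.zeros((5, 4, 4, 4)), block)

    def test_seeded_weights_reproducible(self, tiny_config, db2, rng):
        # regression-style: same seeded model + same phantom -> same weights
        volume = np.random.default_rng(3).random((16, 16, 16))
        runs = []
        for _ in range(2):
            model = build_wavnet(tiny_config, db2)
            model.predict(volume)
            runs.append({k: v.copy() for k, v in model.sa_weights().items()})
        for level in runs[0]:
            assert np.array_equal(runs[0][level], runs[1][level])


class TestPartition:
    def test_partition_covers_all_parameters(self, tiny_model):
        partition = partition_parameters(tiny_model)
        all_names = {n for n, _ in tiny_model.named_parameters()}
        assert partition.adaptable | partition.frozen == all_names
        assert partition.adaptable & partition.frozen == set()
        assert partition.adaptable

    def test_contains_every_sa_parameter(self, tiny_model):
        partition = partition_parameters(tiny_model)
        sa_params = {
            n for n, _ in tiny_model.named_parameters() if n.startswith("sa_blocks.")
        }
        assert sa_params <= partition.adaptable

    def test_adaptable_fraction_below_ten_percent(self, desk_config, db2):
        model = build_wavnet(desk_config, db2)
        n_adapt, n_total = partition_parameters(model).counts(model)
        assert 0 < n_adapt / n_total < 0.1

    def test_no_wavelet_model_refused(self, db2):
        config = NetworkConfig(
            stages=4, encoder_channels=(2, 4, 4, 4), base_resolution=(16, 16, 16),
            use_wavelet=False,
        )
        with pytest.raises(ValueError, match="attention"):
            partition_parameters(build_wavnet(config, db2))

    def test_partition_survives_checkpoint_round_trip(self, tiny_model, tmp_path):
        partition = partition_parameters(tiny_model)
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, tiny_model, {"class_ratio_prior": 0.05})
        loaded, meta = load_checkpoint(path)
        assert set(meta["partition"]["adaptable"]) == partition.adaptable
        assert set(meta["partition"]["frozen"]) == partition.frozen
        assert partition_parameters(loaded).adaptable == partition.adaptable


class TestRefineNet:
    @pytest.mark.parametrize("shape", [(16, 16, 16), (32, 48, 32)])
    def test_output_matches_input_extents(self, shape, rng):
        model = build_refine_model(RefineNetConfig(channels=(2, 4, 4, 4)))
        out = model.predict(rng.random(shape))
        assert out.shape == shape

    def test_output_in_unit_interval(self, rng):
        model = build_refine_model(RefineNetConfig(channels=(2, 4, 4, 4)))
        out = model.predict(rng.random((16, 16, 16)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_untrained_model_gives_finite_refine_loss(self, rng):
        from wavtta.losses import refine_loss

        model = build_refine_model(RefineNetConfig(channels=(2, 4, 4, 4)))
        model.eval()
        value = refine_loss(rng.random((16, 16, 16)), model).item()
        assert np.isfinite(value)

    def test_indivisible_extent_rejected(self, rng):
        model = build_refine_model(RefineNetConfig(channels=(2, 4, 4, 4)))
        with pytest.raises(ConfigurationError, match="divisible"):
            model.forward(rng.random((10, 16, 16)))

    def test_depth_channel_mismatch(self):
        with pytest.raises(ConfigurationError, match="one entry per stage"):
            RefineNetConfig(depth=4, channels=(2, 4)).validate()


class TestCheckpoint:
    def test_state_round_trip_bitwise(self, tiny_model, tiny_volume, tmp_path):
        expected = tiny_model.predict(tiny_volume)
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, tiny_model, {"class_ratio_prior": 0.04})
        loaded, meta = load_checkpoint(path)
        assert meta["class_ratio_prior"] == 0.04
        assert meta["wavelet_family"] == "db2"
        assert np.array_equal(loaded.predict(tiny_volume), expected)

    def test_refine_checkpoint_round_trip(self, tmp_path, rng):
        model = build_refine_model(RefineNetConfig(channels=(2, 4, 4, 4)))
        x = rng.random((16, 16, 16))
        expected = model.predict(x)
        save_checkpoint(tmp_path / "refine.ckpt", model)
        loaded, _ = load_checkpoint(tmp_path / "refine.ckpt")
        assert np.array_equal(loaded.predict(x), expected)
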