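"""Vision-Transformer backbone: geometry, arithmetic oracles, purity."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flatfoot import backbone as bb
from flatfoot.exceptions import (InvalidConfigError, InvalidInputError,
                                 InvalidWeightsError, NumericError)
from flatfoot.samples import ImageSample


class TestPreprocess:
    def test_grayscale_512_becomes_224_rgb(self):
        img = np.random.default_rng(0).integers(0, 256, (512, 512)).astype(np.uint8)
        out = bb.preprocess(img, bb.BackboneConfig())
        assert out.pixels.shape == (224, 224, 3)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_matching_input_returned_unchanged(self):
        img = np.random.default_rng(1).random((224, 224, 3))
        out = bb.preprocess(img, bb.BackboneConfig())
        np.testing.assert_allclose(out.pixels, img, atol=1e-12)

    def test_constant_image_stays_constant_after_resize(self):
        img = np.full((100, 100), 0.3)
        out = bb.preprocess(img, bb.BackboneConfig(image_size=64))
        np.testing.assert_allclose(out.pixels, 0.3, atol=1e-6)

    def test_zero_area_image_rejected(self):
        with pytest.raises(InvalidInputError):
            bb.preprocess(np.empty((0, 5)), bb.BackboneConfig())

    def test_channel_replication(self):
        img = np.random.default_rng(2).random((64, 64, 1))
        out = bb.preprocess(img, bb.BackboneConfig(image_size=64))
        assert np.array_equal(out.pixels[:, :, 0], out.pixels[:, :, 2])


class TestPatchify:
    def test_full_scale_counts(self):
        pix = np.random.default_rng(0).random((224, 224, 3))
        patches = bb.patchify(pix, 16)
        assert patches.shape == (196, 768)

    def test_single_patch_is_flattened_image(self):
        pix = np.random.default_rng(1).random((16, 16, 3))
        patches = bb.patchify(pix, 16)
        np.testing.assert_array_equal(patches[0], pix.reshape(-1))

    def test_constant_image_constant_patches(self):
        patches = bb.patchify(np.full((32, 32, 3), 0.7), 16)
        assert np.all(patches == 0.7)

    def test_reconstruction_roundtrip(self):
        pix = np.random.default_rng(2).random((48, 48, 3))
        patches = bb.patchify(pix, 16)
        np.testing.assert_array_equal(bb.unpatchify(patches, 48, 3), pix)

    def test_nondivisible_side_rejected(self):
        with pytest.raises(InvalidConfigError):
            bb.patchify(np.zeros((30, 30, 3)), 16)


class TestEmbedTokens:
    def test_full_scale_token_count(self):
        rng = np.random.default_rng(0)
        cfg = bb.BackboneConfig(depth=1)
        w = bb.BackboneWeights(
            patch_proj=rng.normal(size=(768, 768)) * 0.02,
            patch_bias=np.zeros(768), cls_token=rng.normal(size=768),
            pos_embed=rng.normal(size=(197, 768)))
        tokens = bb.embed_tokens(rng.random((196, 768)), w)
        assert tokens.shape == (197, 768)

    def test_zero_weights_give_zero_tokens(self):
        w = bb.BackboneWeights(patch_proj=np.zeros((12, 4)),
                               patch_bias=np.zeros(4), cls_token=np.zeros(4),
                               pos_embed=np.zeros((2, 4)))
        tokens = bb.embed_tokens(np.ones((1, 12)), w)
        assert np.all(tokens == 0)

    def test_identity_projection_arithmetic(self):
        # 1 patch, 4-dim toy: token 1 must equal patch + its position row
        patch = np.array([[1.0, -2.0, 0.5, 3.0]])
        pos = np.array([[0.1, 0.1, 0.1, 0.1], [1.0, 2.0, 3.0, 4.0]])
        w = bb.BackboneWeights(patch_proj=np.eye(4), patch_bias=np.zeros(4),
                               cls_token=np.zeros(4), pos_embed=pos)
        tokens = bb.embed_tokens(patch, w)
        np.testing.assert_allclose(tokens[1], patch[0] + pos[1], atol=1e-12)
        np.testing.assert_allclose(tokens[0], pos[0], atol=1e-12)

    def test_position_row_mismatch_rejected(self):
        w = bb.BackboneWeights(patch_proj=np.eye(4), patch_bias=np.zeros(4),
                               cls_token=np.zeros(4), pos_embed=np.zeros((3, 4)))
        with pytest.raises(InvalidWeightsError):
            bb.embed_tokens(np.ones((1, 4)), w)


class TestScaledAttention:
    def test_single_key_value_returns_value(self):
        q = np.random.default_rng(0).random((3, 4))
        k = np.random.default_rng(1).random((1, 4))
        v = np.array([[2.0, -1.0]])
        out = bb.scaled_attention(q, k, v)
        np.testing.assert_allclose(out, np.repeat(v, 3, axis=0), atol=1e-12)

    def test_zero_queries_give_value_column_means(self):
        v = np.random.default_rng(2).random((5, 3))
        out = bb.scaled_attention(np.zeros((2, 4)),
                                  np.random.default_rng(3).random((5, 4)), v)
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (2, 1)),
                                   atol=1e-12)

    def test_two_token_scalar_oracle(self):
        # head_dim 1: scores and softmax recomputed with scalar math
        import math
        Q = np.array([[1.0], [0.0]])
        K = np.array([[1.0], [0.0]])
        V = np.array([[1.0], [3.0]])
        out = bb.scaled_attention(Q, K, V)
        for i, q in enumerate((1.0, 0.0)):
            s1, s2 = q * 1.0, q * 0.0          # / sqrt(1)
            e1, e2 = math.exp(s1), math.exp(s2)
            expect = (e1 * 1.0 + e2 * 3.0) / (e1 + e2)
            assert abs(out[i, 0] - expect) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            bb.scaled_attention(np.empty((0, 2)), np.empty((0, 2)),
                                np.empty((0, 2)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_softmax_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n, m, d = rng.integers(1, 8, size=3)
        q, k = rng.normal(size=(n, d)) * 5, rng.normal(size=(m, d)) * 5
        scores = bb.softmax(q @ k.T / np.sqrt(d), axis=-1)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


class TestEncoderBlock:
    @staticmethod
    def _zero_block(d, nh):
        hd = d // nh
        z = np.zeros
        return bb.BlockWeights(
            ln1_gamma=np.ones(d), ln1_beta=z(d),
            wq=z((nh, d, hd)), bq=z((nh, hd)), wk=z((nh, d, hd)),
            bk=z((nh, hd)), wv=z((nh, d, hd)), bv=z((nh, hd)),
            wo=z((d, d)), bo=z(d), ln2_gamma=np.ones(d), ln2_beta=z(d),
            mlp_w1=z((d, 4 * d)), mlp_b1=z(4 * d), mlp_w2=z((4 * d, d)),
            mlp_b2=z(d))

    def test_zero_weights_identity(self):
        tokens = np.random.default_rng(0).normal(size=(7, 8))
        out = bb.encoder_block(tokens, self._zero_block(8, 2))
        np.testing.assert_allclose(out, tokens, atol=1e-12)

    def test_shape_preserved_at_full_scale(self):
        cfg = bb.BackboneConfig(depth=1)
        w = bb.init_backbone(cfg, seed=0)
        tokens = np.random.default_rng(1).normal(size=(197, 768))
        out = bb.encoder_block(tokens, w.blocks[0])
        assert out.shape == (197, 768)

    def test_deterministic(self, toy_weights):
        tokens = np.random.default_rng(2).normal(size=(5, 8))
        a = bb.encoder_block(tokens, toy_weights.blocks[0])
        b = bb.encoder_block(tokens, toy_weights.blocks[0])
        np.testing.assert_array_equal(a, b)

    def test_nan_input_rejected(self, toy_weights):
        tokens = np.full((5, 8), np.nan)
        with pytest.raises(NumericError):
            bb.encoder_block(tokens, toy_weights.blocks[0])


class TestForwardFeatures:
    def test_default_config_emits_1000_features(self):
        cfg = bb.BackboneConfig()
        w = bb.init_backbone(cfg, seed=0)
        sample = bb.preprocess(np.random.default_rng(0).random((224, 224, 3)),
                               cfg)
        feats = bb.forward_features(sample, w, cfg)
        assert feats.shape == (1000,)
        assert np.isfinite(feats).all()

    def test_toy_config_feature_length(self, toy_config, toy_weights):
        sample = bb.preprocess(np.random.default_rng(1).random((32, 32, 3)),
                               toy_config)
        assert bb.forward_features(sample, toy_weights, toy_config).shape == (10,)

    def test_pure_function(self, toy_config, toy_weights):
        sample = bb.preprocess(np.random.default_rng(2).random((32, 32, 3)),
                               toy_config)
        a = bb.forward_features(sample, toy_weights, toy_config)
        b = bb.forward_features(sample, toy_weights, toy_config)
        np.testing.assert_array_equal(a, b)

    def test_unpreprocessed_sample_rejected(self, toy_config, toy_weights):
        with pytest.raises(InvalidWeightsError):
            bb.forward_features(ImageSample(pixels=np.zeros((64, 64, 3))),
                                toy_weights, toy_config)


class TestInitBackbone:
    def test_reproducible_from_seed(self, toy_config):
        a = bb.init_backbone(toy_config, seed=9)
        b = bb.init_backbone(toy_config, seed=9)
        np.testing.assert_array_equal(a.patch_proj, b.patch_proj)
        np.testing.assert_array_equal(a.blocks[1].mlp_w1, b.blocks[1].mlp_w1)

    def test_different_seeds_differ(self, toy_config):
        a = bb.init_backbone(toy_config, seed=1)
        b = bb.init_backbone(toy_config, seed=2)
        assert not np.array_equal(a.patch_proj, b.patch_proj)

    def test_toy_position_rows(self, toy_config, toy_weights):
        assert toy_config.n_tokens == (32 // 16) ** 2 + 1 == 5
        assert toy_weights.pos_embed.shape == (5, 8)

    @pytest.mark.parametrize("image,patch,expected",
                             [(224, 16, 197), (32, 16, 5), (64, 8, 65)])
    def test_token_count_formula(self, image, patch, expected):
        cfg = bb.BackboneConfig(image_size=image, patch_size=patch,
                                embed_dim=8, n_heads=2, depth=1, feature_dim=4)
        assert cfg.n_tokens == expected

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidConfigError):
            bb.BackboneConfig(image_size=224, patch_size=15)
        with pytest.raises(InvalidConfigError):
            bb.BackboneConfig(embed_dim=10, n_heads=3)


class TestCheckpointInterop:
    def test_named_array_roundtrip(self, toy_config, toy_weights):
        named = bb.weights_to_named_arrays(toy_weights)
        back = bb.weights_from_named_arrays(named, toy_config)
        sample = bb.preprocess(np.random.default_rng(3).random((32, 32, 3)),
                               toy_config)
        np.testing.assert_array_equal(
            bb.forward_features(sample, toy_weights, toy_config),
            bb.forward_features(sample, back, toy_config))

    def test_vit_b16_name_adapter(self, toy_config):
        # synthetic checkpoint in the common fused-qkv naming scheme
        rng = np.random.default_rng(4)
        d, nh, hd, p, c = 8, 2, 4, 16, 3
        arrays = {
            "patch_embed.proj.weight": rng.normal(size=(d, c, p, p)),
            "patch_embed.proj.bias": rng.normal(size=d),
            "cls_token": rng.normal(size=(1, 1, d)),
            "pos_embed": rng.normal(size=(1, 5, d)),
            "norm.weight": np.ones(d), "norm.bias": np.zeros(d),
            "head.weight": rng.normal(size=(10, d)),
            "head.bias": np.zeros(10),
        }
        for i in range(2):
            arrays.update({
                f"blocks.{i}.norm1.weight": np.ones(d),
                f"blocks.{i}.norm1.bias": np.zeros(d),
                f"blocks.{i}.attn.qkv.weight": rng.normal(size=(3 * d, d)),
                f"blocks.{i}.attn.qkv.bias": rng.normal(size=3 * d),
                f"blocks.{i}.attn.proj.weight": rng.normal(size=(d, d)),
                f"blocks.{i}.attn.proj.bias": np.zeros(d),
                f"blocks.{i}.norm2.weight": np.ones(d),
                f"blocks.{i}.norm2.bias": np.zeros(d),
                f"blocks.{i}.mlp.fc1.weight": rng.normal(size=(4 * d, d)),
                f"blocks.{i}.mlp.fc1.bias": np.zeros(4 * d),
                f"blocks.{i}.mlp.fc2.weight": rng.normal(size=(d, 4 * d)),
                f"blocks.{i}.mlp.fc2.bias": np.zeros(d),
            })
        w = bb.weights_from_vit_b16_names(arrays, toy_config)
        # fused qkv rows split into per-head projections consistently
        q0 = arrays["blocks.0.attn.qkv.weight"][:d]
        np.testing.assert_allclose(w.blocks[0].wq[0], q0.T[:, :hd])
        sample = bb.preprocess(np.random.default_rng(5).random((32, 32, 3)),
                               toy_config)
        feats = bb.forward_features(sample, w, toy_config)
        assert feats.shape == (10,) and np.isfinite(feats).all()

    def test_missing_array_reported(self, toy_config):
        with pytest.raises(InvalidWeightsError):
            bb.weights_from_named_arrays({"cls_token": np.zeros(8)}, toy_config)
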