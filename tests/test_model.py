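"""ViT backbone: patchification, embedding, forward contracts, checkpoints."""

import numpy as np
import pytest

from atsvit.model import PatchGrid, ViTATS, ViTConfig, patchify, unpatchify


class TestPatchify:
    def test_full_scale_grid(self, rng):
        img = rng.random((256, 256))
        patches = patchify(img, 16)
        assert patches.shape == (256, 256)  # 256 patches of 16*16*1

    def test_roundtrip_exact(self, rng):
        img = rng.random((64, 64, 3))
        patches = patchify(img, 16)
        assert patches.shape == (16, 16 * 16 * 3)
        np.testing.assert_array_equal(unpatchify(patches, 64, 3, 16), img)

    def test_single_patch_is_flat_image(self, rng):
        img = rng.random((16, 16))
        patches = patchify(img, 16)
        np.testing.assert_array_equal(patches[0], img.ravel())

    def test_indivisible_size_raises(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            patchify(rng.random((60, 60)), 16)
        with pytest.raises(ValueError):
            PatchGrid(image_size=60, channels=1, patch_size=16)


class TestEmbed:
    def test_token_count_is_patches_plus_cls(self, tiny_model, rng):
        x = tiny_model.embed(rng.random((64, 64)))
        assert x.shape == (17, 32)

    def test_position_encoding_breaks_permutation_symmetry(self, tiny_model, rng):
        img = rng.random((64, 64))
        # swap two patch blocks
        img2 = img.copy()
        img2[:16, :16], img2[:16, 16:32] = img[:16, 16:32].copy(), img[:16, :16].copy()
        x1 = tiny_model.embed(img).data
        x2 = tiny_model.embed(img2).data
        assert not np.allclose(x1, x2)

    def test_zero_image_embeddings_are_bias_plus_position(self, tiny_model):
        x = tiny_model.embed(np.zeros((64, 64))).data
        expected = (tiny_model.params["embed_b"].data
                    + tiny_model.params["pos"].data)
        np.testing.assert_allclose(x[1:], expected, atol=1e-12)
        np.testing.assert_allclose(x[0], tiny_model.params["cls"].data)


class TestForward:
    def test_ats_off_keeps_token_count_constant(self, rng):
        cfg = ViTConfig(image_size=64, channels=1, patch_size=16, dim=32,
                        depth=3, heads=2, num_classes=2, token_schedule=None)
        model = ViTATS(cfg)
        _, tokens, info = model.forward_single(rng.random((64, 64)))
        assert tokens.shape[0] == 17
        assert info["token_counts"] == [17, 17, 17]

    def test_schedule_bounds_token_counts(self, rng):
        cfg = ViTConfig(image_size=256, channels=1, patch_size=16, dim=32,
                        depth=6, heads=2, num_classes=3,
                        token_schedule=(256, 128, 64, 32, 16, 8))
        model = ViTATS(cfg)
        _, tokens, info = model.forward_single(rng.random((256, 256)),
                                               mode="stochastic")
        bounds = [257, 129, 65, 33, 17, 9]
        assert all(c <= b for c, b in zip(info["token_counts"], bounds))
        assert tokens.shape[0] == info["token_counts"][-1]

    def test_deterministic_mode_is_deterministic(self, tiny_model, rng):
        img = rng.random((64, 64))
        logits, _, _ = tiny_model.forward([img, img], mode="deterministic")
        np.testing.assert_array_equal(logits.data[0], logits.data[1])

    def test_full_budget_matches_ats_off(self, rng):
        """K >= N in every block reduces to a plain ViT."""
        img = rng.random((64, 64))
        kw = dict(image_size=64, channels=1, patch_size=16, dim=32, depth=2,
                  heads=2, num_classes=2, seed=3)
        on = ViTATS(ViTConfig(token_schedule=(16, 16), **kw))
        off = ViTATS(ViTConfig(token_schedule=None, **kw))
        lo_on, _, _ = on.forward_single(img, mode="deterministic")
        lo_off, _, _ = off.forward_single(img)
        np.testing.assert_allclose(lo_on.data, lo_off.data, atol=1e-12)

    def test_every_parameter_gets_finite_gradient(self, tiny_model, rng):
        imgs = [rng.random((64, 64)) for _ in range(2)]
        logits, _, _ = tiny_model.forward(imgs, mode="stochastic")
        loss = logits.bce_with_logits(np.array([[1.0, 0.0], [0.0, 1.0]]))
        loss.backward()
        for name, p in tiny_model.params.items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name

    def test_schedule_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="schedule length"):
            ViTConfig(image_size=64, channels=1, patch_size=16, dim=32,
                      depth=3, heads=2, num_classes=2, token_schedule=(16, 8))


class TestTopTokens:
    def test_boxes_disjoint_and_in_bounds(self, tiny_model, rng):
        img = rng.random((64, 64))
        coords = tiny_model.top_tokens(img, k=4)
        boxes = tiny_model.patch_boxes(coords)
        assert len(set(coords)) == 4
        for y0, x0, y1, x1 in boxes:
            assert 0 <= y0 < y1 <= 64 and 0 <= x0 < x1 <= 64

    def test_k_exceeding_budget_raises(self, tiny_model, rng):
        with pytest.raises(ValueError, match="exceeds"):
            tiny_model.top_tokens(rng.random((64, 64)), k=12)

    def test_requires_ats(self, rng):
        cfg = ViTConfig(image_size=64, channels=1, patch_size=16, dim=32,
                        depth=2, heads=2, num_classes=2, token_schedule=None)
        with pytest.raises(ValueError, match="token sampling"):
            ViTATS(cfg).top_tokens(rng.random((64, 64)), k=4)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tiny_model, rng, tmp_path):
        img = rng.random((64, 64))
        before, _, _ = tiny_model.forward_single(img, mode="deterministic")
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        restored = ViTATS.load(path)
        assert restored.config == tiny_model.config
        after, _, _ = restored.forward_single(img, mode="deterministic")
        np.testing.assert_array_equal(before.data, after.data)

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "bogus.npz"
        np.savez(path, __header__=np.frombuffer(b'{"format": "x"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="checkpoint"):
            ViTATS.load(path)
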