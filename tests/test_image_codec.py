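"""Binarization, quantization and codec round-trip behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from seq2loc.evaluation import iou
from seq2loc.image_codec import (Codebook, CodecConfig, TokenGrid, VQCodec,
                                 binarize, quantize, train_codec)


class TestBinarize:
    @pytest.mark.parametrize("image,expected", [
        ([[1, 2], [3, 6]], [[0, 0], [1, 1]]),          # mean 3, >= inclusive
        ([[5, 5], [5, 5]], [[1, 1], [1, 1]]),          # constant -> all ones
        ([[0, 1], [1, 0]], [[0, 1], [1, 0]]),          # already binary
    ])
    def test_mean_threshold_rule(self, image, expected):
        np.testing.assert_array_equal(binarize(np.array(image, float)),
                                      np.array(expected, float))

    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
    def test_idempotent_and_shape_preserving(self, image):
        once = binarize(image)
        assert once.shape == image.shape
        np.testing.assert_array_equal(binarize(once), once)
        if not np.allclose(image, image.flat[0]):
            assert 0.0 < once.mean() <= 1.0

    def test_rejects_empty_and_nan(self):
        with pytest.raises(ValueError):
            binarize(np.empty((0, 0)))
        with pytest.raises(ValueError):
            binarize(np.array([[np.nan, 1.0]]))


class TestQuantize:
    def test_nearest_neighbor_and_ties(self):
        book = Codebook(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert quantize(np.array([1.9, 2.1]), book) == 1
        assert quantize(np.array([0.0, 0.0]), book) == 0
        assert quantize(np.array([1.0, 1.0]), book) == 0  # tie -> lowest index

    def test_matches_exhaustive_search(self, rng):
        book = Codebook(rng.normal(size=(32, 8)))
        for _ in range(50):
            v = rng.normal(size=8)
            brute = min(range(32),
                        key=lambda i: float(((book.vectors[i] - v) ** 2).sum()))
            assert quantize(v, book) == brute

    def test_self_quantization_identity(self, rng):
        book = Codebook(rng.normal(size=(16, 4)))
        for i in range(16):
            assert quantize(book.vectors[i], book) == i

    def test_dimension_mismatch_rejected(self, rng):
        book = Codebook(rng.normal(size=(4, 8)))
        with pytest.raises(ValueError):
            quantize(np.zeros(5), book)


class TestTokenCounts:
    def test_production_preset_token_count(self):
        """A 256x256 image in 16x16-pixel patches yields 256 tokens."""
        codec = VQCodec(CodecConfig(patch_edge=16, n_codes=8))
        grid = codec.encode(np.zeros((256, 256)))
        assert grid.flatten().size == 256

    def test_mini_preset_token_count(self):
        codec = VQCodec(CodecConfig(patch_edge=8, n_codes=8))
        assert codec.encode(np.zeros((64, 64))).flatten().size == 64

    def test_shape_mismatch_rejected(self):
        codec = VQCodec(CodecConfig(patch_edge=8))
        with pytest.raises(ValueError, match="divisible"):
            codec.encode(np.zeros((60, 60)))


class TestDecode:
    def test_decode_deterministic_and_out_of_range_rejected(self):
        codec = VQCodec(CodecConfig(patch_edge=8, n_codes=8))
        grid = TokenGrid(np.zeros((8, 8), dtype=int))
        np.testing.assert_array_equal(codec.decode(grid), codec.decode(grid))
        with pytest.raises(ValueError):
            codec.decode(TokenGrid(np.full((8, 8), 99)))

    def test_codebook_permutation_symmetry(self):
        codec = VQCodec(CodecConfig(patch_edge=8, n_codes=8))
        grid = TokenGrid(np.random.default_rng(0).integers(0, 8, (8, 8)))
        before = codec.decode(grid)
        # swap entries 2 and 5 and relabel the grid accordingly
        codec.codebook_vectors[[2, 5]] = codec.codebook_vectors[[5, 2]]
        relabeled = grid.indices.copy()
        relabeled[grid.indices == 2], relabeled[grid.indices == 5] = 5, 2
        after = codec.decode(TokenGrid(relabeled))
        np.testing.assert_allclose(before, after)


class TestTrainedCodec:
    def test_loss_decreases(self, threshold_codec):
        curve = threshold_codec._loss_curve
        assert curve[-1] < curve[0]

    def test_roundtrip_token_agreement(self, threshold_codec, train_records):
        """encode(decode(T)) must reproduce T for grids of real images."""
        agreements = []
        for r in train_records[160:192]:
            grid = threshold_codec.encode(binarize(r.protein_image))
            again = threshold_codec.encode(threshold_codec.decode(grid))
            agreements.append((again.indices == grid.indices).mean())
        assert np.mean(agreements) >= 0.99

    def test_reconstruction_iou_on_heldout(self, threshold_codec, train_records):
        ious = []
        for r in train_records[160:192]:  # unseen by this codec
            u = binarize(r.protein_image)
            recon = binarize(threshold_codec.decode(threshold_codec.encode(u)))
            ious.append(iou(recon, u))
        assert np.mean(ious) >= 0.7

    def test_beats_shuffled_grid_baseline(self, threshold_codec, train_records,
                                          rng):
        real, shuffled = [], []
        for r in train_records[160:192]:
            u = binarize(r.protein_image)
            grid = threshold_codec.encode(u)
            real.append(iou(binarize(threshold_codec.decode(grid)), u))
            perm = rng.permutation(grid.flatten()).reshape(grid.indices.shape)
            shuffled.append(
                iou(binarize(threshold_codec.decode(TokenGrid(perm))), u))
        assert np.mean(real) - np.mean(shuffled) >= 0.3

    def test_save_load_roundtrip(self, threshold_codec, tmp_path):
        path = tmp_path / "codec.npz"
        threshold_codec.save(path)
        loaded = VQCodec.load(path)
        assert loaded.checksum() == threshold_codec.checksum()
        img = np.random.default_rng(0).random((64, 64))
        np.testing.assert_array_equal(loaded.encode(img).indices,
                                      threshold_codec.encode(img).indices)


def test_adversarial_term_trains_without_destabilizing():
    rng = np.random.default_rng(0)
    imgs = [rng.random((16, 16)) for _ in range(16)]
    cfg = CodecConfig(patch_edge=8, n_codes=8, latent_dim=4, hidden=16,
                      epochs=3, adversarial_weight=0.1, seed=1)
    codec, curve = train_codec(imgs, "threshold", cfg)
    assert np.isfinite(curve).all()


def test_train_codec_requires_enough_images():
    with pytest.raises(ValueError, match="16"):
        train_codec([np.zeros((16, 16))] * 4, "threshold",
                    CodecConfig(patch_edge=8, epochs=1))
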