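"""Patch partitioning and attention-difference attribution."""

import numpy as np
import pytest

from seq2loc.attribution import (ResidueAttribution, attention_difference,
                                 motif_report, partition_patches)
from seq2loc.core_transformer import StreamLayout


class TestPartitionPatches:
    def test_bright_quadrant_selected_by_global_mean(self):
        img = np.zeros((16, 16))
        img[:8, :8] = 1.0  # top-left quadrant bright
        part = partition_patches(img, patch_edge=4)
        # grid is 4x4; top-left quadrant = positions {0,1,4,5}
        assert set(part.present_ids.tolist()) == {0, 1, 4, 5}
        assert len(part.absent_ids) == 12

    def test_all_ones_image_degenerate_but_allowed(self):
        part = partition_patches(np.ones((8, 8)), patch_edge=4)
        assert len(part.present_ids) == 4
        assert len(part.absent_ids) == 0

    def test_binary_image_absolute_cutoff(self):
        img = np.zeros((8, 8))
        img[0:4, 0:4] = 1.0          # patch 0 fully on
        img[0:2, 4:8] = 1.0          # patch 1 half on
        part = partition_patches(img, patch_edge=4, cutoff=0.5)
        assert 0 in part.present_ids and 1 in part.present_ids
        assert 2 in part.absent_ids and 3 in part.absent_ids

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            partition_patches(np.empty((0, 0)), patch_edge=4)


def make_layout():
    return StreamLayout(L_max=6, g2=4)  # T = 14


def uniform_attention(layout, layers=2, heads=2):
    T = layout.T
    return np.full((layers, heads, T, T), 1.0 / T)


def make_partition(present, absent):
    from seq2loc.attribution import PatchPartition

    return PatchPartition(present_ids=np.array(present),
                          absent_ids=np.array(absent), cutoff=0.5)


class TestAttentionDifference:
    def test_uniform_attention_gives_zero_scores(self):
        lay = make_layout()
        attn = uniform_attention(lay)
        res = attention_difference(attn, make_partition([0, 1], [2, 3]), lay,
                                   seq_length=4)
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)

    def test_constructed_focus_on_single_residue(self):
        lay = make_layout()
        attn = uniform_attention(lay)
        r5 = lay.seq_pos(3)
        for j in (0, 1):  # present-patch queries attend heavily to residue 3
            q = lay.prot_query_pos(j)
            attn[:, :, q, :] = 0.0
            attn[:, :, q, r5] = 1.0
        res = attention_difference(attn, make_partition([0, 1], [2, 3]), lay,
                                   seq_length=4)
        assert res.scores[3] > 0
        assert np.all(res.scores[np.arange(4) != 3] <= res.scores[3])

    def test_matches_bruteforce_double_loop(self, rng):
        """Oracle: explicit loops over (layer, head, query, key)."""
        lay = make_layout()
        L, H, T = 2, 2, lay.T
        raw = rng.random((L, H, T, T))
        attn = raw / raw.sum(axis=-1, keepdims=True)
        part = make_partition([0, 3], [1, 2])
        seq_len = 5
        res = attention_difference(attn, part, lay, seq_length=seq_len)
        brute = np.zeros(seq_len)
        for r in range(seq_len):
            key = lay.seq_pos(r)
            vals_p, vals_a = [], []
            for l in range(L):
                for h in range(H):
                    for j in part.present_ids:
                        vals_p.append(attn[l, h, lay.prot_query_pos(j), key])
                    for j in part.absent_ids:
                        vals_a.append(attn[l, h, lay.prot_query_pos(j), key])
            brute[r] = np.mean(vals_p) - np.mean(vals_a)
        np.testing.assert_allclose(res.scores, brute, atol=1e-8)

    def test_swapping_groups_negates_scores(self, rng):
        lay = make_layout()
        raw = rng.random((2, 2, lay.T, lay.T))
        attn = raw / raw.sum(axis=-1, keepdims=True)
        a = attention_difference(attn, make_partition([0, 1], [2, 3]), lay, 4)
        b = attention_difference(attn, make_partition([2, 3], [0, 1]), lay, 4)
        np.testing.assert_allclose(a.scores, -b.scores, atol=1e-12)

    def test_invariant_to_layer_and_head_permutation(self, rng):
        lay = make_layout()
        raw = rng.random((3, 2, lay.T, lay.T))
        attn = raw / raw.sum(axis=-1, keepdims=True)
        part = make_partition([0], [1, 2, 3])
        a = attention_difference(attn, part, lay, 4)
        shuffled = attn[[2, 0, 1]][:, [1, 0]]
        b = attention_difference(shuffled, part, lay, 4)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_one_sided_partition_rejected(self, rng):
        lay = make_layout()
        attn = uniform_attention(lay)
        with pytest.raises(ValueError, match="cutoff"):
            attention_difference(attn, make_partition([0, 1, 2, 3], []), lay, 4)


class TestMotifReport:
    def make_attr(self, scores):
        scores = np.asarray(scores, float)
        return ResidueAttribution(scores=scores, highlighted=np.array([]),
                                  display_threshold=0.0)

    def test_delta_peak_yields_single_segment(self):
        scores = np.zeros(20)
        scores[10] = 5.0
        report = motif_report(self.make_attr(scores), "A" * 20, window=1)
        assert len(report) == 1
        assert (report.iloc[0]["start"], report.iloc[0]["end"]) == (10, 10)

    def test_flat_scores_yield_no_segments(self):
        report = motif_report(self.make_attr(np.ones(15)), "A" * 15, window=3)
        assert len(report) == 0

    def test_segments_ranked_by_peak(self):
        scores = np.zeros(30)
        scores[5] = 2.0
        scores[20] = 8.0
        report = motif_report(self.make_attr(scores), "A" * 30, window=1)
        assert report.iloc[0]["start"] == 20

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="window"):
            motif_report(self.make_attr(np.zeros(4)), "AAAA", window=5)
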