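"""Stream construction, causality, attention and likelihood invariants."""

import dataclasses

import numpy as np
import pytest

from seq2loc.core_transformer import (ModelConfig, StreamLayout, Transformer,
                                      provider_checksum, train_transformer)
from seq2loc.image_codec import TokenGrid
from seq2loc.sequence_embed import LookupTableProvider, embed


TINY = ModelConfig(L_max=10, grid_edge=2, n_ref=8, n_prot=8, width=16,
                   n_layers=2, n_heads=2, seed=3)


@pytest.fixture(scope="module")
def tiny_model():
    return Transformer(TINY)


@pytest.fixture(scope="module")
def tiny_provider():
    return LookupTableProvider(seed=0, d_seq=TINY.width)


def make_stream(model, provider, seed=0, seq="MKKLVRAG"):
    rng = np.random.default_rng(seed)
    g = model.config.grid_edge
    ref = TokenGrid(rng.integers(0, model.config.n_ref, (g, g)))
    prot = TokenGrid(rng.integers(0, model.config.n_prot, (g, g)))
    emb = embed(seq, provider, L_max=model.config.L_max)
    return model.assemble_stream(emb, ref, prot)


class TestStreamLayout:
    def test_production_scale_stream_length(self):
        """1 start + 1000 residues + 256 reference + 255 protein = 1512."""
        assert StreamLayout(L_max=1000, g2=256).T == 1512

    def test_mini_scale_stream_length(self):
        assert StreamLayout(L_max=100, g2=64).T == 228

    def test_last_position_predicts_final_protein_token(self):
        lay = StreamLayout(L_max=10, g2=4)
        # targets at the protein slice cover all g2 protein tokens and the
        # final input position predicts the g2-th one
        assert lay.prot_target_slice.stop == lay.T
        assert lay.prot_query_pos(lay.g2 - 1) == lay.T - 1

    def test_segment_ids_partition_the_stream(self):
        lay = StreamLayout(L_max=10, g2=4)
        seg = lay.segment_ids()
        assert (seg == 0).sum() == 1
        assert (seg == 1).sum() == 10
        assert (seg == 2).sum() == 4
        assert (seg == 3).sum() == 3


class TestForward:
    def test_untrained_model_emits_uniform_logits(self, tiny_model,
                                                  tiny_provider):
        """Zero-initialized output heads give exactly ln(n) cross-entropy."""
        stream = make_stream(tiny_model, tiny_provider)
        total, per_pos = tiny_model.joint_log_likelihood(stream)
        np.testing.assert_allclose(-per_pos, np.log(TINY.n_prot), atol=1e-9)

    def test_causality_at_segment_boundaries(self, tiny_provider):
        """Perturbing the input at position t must not change logits before t."""
        tiny_model = Transformer(TINY)
        rng = np.random.default_rng(0)
        tiny_model.head_ref.data[...] = rng.normal(size=tiny_model.head_ref.shape)
        tiny_model.head_prot.data[...] = rng.normal(size=tiny_model.head_prot.shape)
        stream = make_stream(tiny_model, tiny_provider)
        ref_base, prot_base = tiny_model.forward(stream)
        lay = tiny_model.config.layout
        # positions just after each segment boundary: first sequence slot,
        # first reference slot, first protein slot, and a late protein slot
        for t in (1, 1 + TINY.L_max, 1 + TINY.L_max + lay.g2, lay.T - 1):
            perturbed = dataclasses.replace(stream)
            perturbed.inputs = stream.inputs.copy()
            perturbed.inputs[t] += 10.0
            ref_new, prot_new = tiny_model.forward(perturbed)
            all_logits_base = np.concatenate([ref_base, prot_base])
            all_logits_new = np.concatenate([ref_new, prot_new])
            # logits at output positions strictly before t are untouched;
            # output row i sits at stream position i + L_max
            n_before = max(0, t - TINY.L_max)
            np.testing.assert_array_equal(all_logits_new[:n_before],
                                          all_logits_base[:n_before])
            assert (all_logits_new[n_before:] != all_logits_base[n_before:]).any()

    def test_attention_rows_stochastic_and_future_masked(self, tiny_model,
                                                         tiny_provider):
        stream = make_stream(tiny_model, tiny_provider)
        _, _, attn = tiny_model.forward(stream, capture_attention=True)
        T = tiny_model.config.layout.T
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)
        future = np.triu(np.ones((T, T), bool), k=1)
        assert np.all(attn[:, :, future] == 0.0)

    def test_padded_positions_receive_no_attention(self, tiny_model,
                                                   tiny_provider):
        stream = make_stream(tiny_model, tiny_provider, seq="MKV")
        _, _, attn = tiny_model.forward(stream, capture_attention=True)
        padded = np.arange(1 + 3, 1 + TINY.L_max)
        assert np.all(attn[:, :, TINY.L_max:, padded] == 0.0)

    def test_graph_and_numpy_forward_agree(self, tiny_model, tiny_provider):
        """The differentiable training path and the inference path are the
        same function."""
        stream = make_stream(tiny_model, tiny_provider)
        x = tiny_model._embed_batch_graph([stream])
        h = tiny_model._forward_graph(x, stream.attention_mask[None])
        lay = tiny_model.config.layout
        prot_graph = (h.data[0, lay.prot_target_slice]
                      @ tiny_model.head_prot.data + tiny_model.head_prot_b.data)
        _, prot_np = tiny_model.forward(stream)
        np.testing.assert_allclose(prot_graph, prot_np, atol=1e-10)

    def test_incremental_decode_matches_full_forward(self, tiny_model,
                                                     tiny_provider):
        """Autoregressive factorization: KV-cached per-position logits equal
        the teacher-forced pass, so per-position log-probs sum to the joint."""
        stream = make_stream(tiny_model, tiny_provider)
        cfg = tiny_model.config
        prefix = 1 + cfg.L_max + cfg.g2
        cache = tiny_model.init_cache(stream.inputs[:prefix],
                                      stream.attention_mask[:prefix])
        incremental = [tiny_model.prot_logits_from_hidden(cache._hidden_last)]
        for j in range(cfg.g2 - 1):
            tok = stream.prot_targets[j]
            hidden = cache.append(tiny_model.prot_input_vector(tok, j))
            incremental.append(tiny_model.prot_logits_from_hidden(hidden))
        _, prot_full = tiny_model.forward(stream)
        np.testing.assert_allclose(np.stack(incremental), prot_full, atol=1e-8)
        total, per_pos = tiny_model.joint_log_likelihood(stream)
        assert total == pytest.approx(per_pos.sum(), abs=1e-4)

    def test_grid_size_mismatch_rejected(self, tiny_model, tiny_provider):
        emb = embed("MKV", tiny_provider, L_max=TINY.L_max)
        with pytest.raises(ValueError, match="grid"):
            tiny_model.assemble_stream(emb, TokenGrid(np.zeros((3, 3), int)))


class TestTraining:
    def test_loss_drops_and_frozen_components_verified(self, tiny_provider):
        cfg = dataclasses.replace(TINY, steps=30, batch_size=4, lr=5e-3,
                                  warmup=5)
        model = Transformer(cfg)
        streams = [make_stream(model, tiny_provider, seed=s) for s in range(8)]
        frozen = {"provider": provider_checksum(tiny_provider)}
        model, history = train_transformer(
            streams, cfg, frozen_checksums=frozen,
            recheck={"provider": lambda: provider_checksum(tiny_provider)},
            model=model)
        assert history[-1]["prot_ce"] < history[0]["prot_ce"]

    def test_mutated_frozen_component_aborts(self, tiny_provider):
        cfg = dataclasses.replace(TINY, steps=2, batch_size=2)
        model = Transformer(cfg)
        streams = [make_stream(model, tiny_provider, seed=s) for s in range(4)]
        with pytest.raises(RuntimeError, match="frozen"):
            train_transformer(streams, cfg,
                              frozen_checksums={"provider": "stale"},
                              recheck={"provider": lambda: "changed"},
                              model=model)

    def test_optional_residue_head_contributes_loss(self, tiny_provider):
        cfg = dataclasses.replace(TINY, seq_loss_weight=0.5)
        model = Transformer(cfg)
        streams = [make_stream(model, tiny_provider, seed=s) for s in range(2)]
        _, parts = model.loss(streams)
        assert "seq_ce" in parts
        assert parts["total"] == pytest.approx(
            parts["prot_ce"] + cfg.ref_loss_weight * parts["ref_ce"]
            + 0.5 * parts["seq_ce"], abs=1e-9)

    def test_save_load_preserves_checksum(self, tiny_model, tmp_path):
        tiny_model.save(tmp_path / "m.npz")
        loaded = Transformer.load(tmp_path / "m.npz")
        assert loaded.checksum() == tiny_model.checksum()
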