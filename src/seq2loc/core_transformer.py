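"""Decoder-only autoregressive transformer over the joint token stream.

The model learns the joint distribution over a single concatenated stream

    [START] + amino-acid embeddings (L_max) + reference-image tokens (g^2)
            + protein-threshold tokens (g^2 - 1)

where a learned start vector is prepended and the final protein token is
dropped from the input, so that with the usual shift-by-one targets the
last input position predicts the g^2-th protein token.  Amino-acid
positions carry frozen continuous embeddings from the sequence provider;
image-token positions carry learned embedding tables cast to the same
width, plus learned per-segment positional embeddings.

Training teacher-forces the whole stream and minimizes cross-entropy over
image-token targets (reference and protein codebooks each through their
own output head).  A 21-way residue head over amino-acid positions is
available but carries zero loss weight by default: the sequence inputs are
continuous frozen embeddings, so only image-token likelihoods conditioned
on the sequence are modeled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import AdamW, Parameter, Tensor
from .image_codec import TokenGrid
from .sequence_embed import ALPHABET, SequenceEmbedding

__all__ = ["StreamLayout", "ModelConfig", "TokenStream", "Transformer",
           "train_transformer", "provider_checksum"]


# ---------------------------------------------------------------------------
# stream layout
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StreamLayout:
    """Index bookkeeping for the concatenated token stream."""

    L_max: int
    g2: int  # tokens per image grid

    @property
    def T(self) -> int:
        # 1 (start) + L_max + g2 (reference) + g2 - 1 (protein, last removed)
        return self.L_max + 2 * self.g2

    # input positions of each segment
    @property
    def start_pos(self) -> int:
        return 0

    def seq_pos(self, r: int) -> int:
        return 1 + r

    def ref_pos(self, j: int) -> int:
        return 1 + self.L_max + j

    def prot_pos(self, j: int) -> int:
        """Input position holding protein token j (j < g2 - 1)."""
        return 1 + self.L_max + self.g2 + j

    # target positions: position t predicts stream element t + 1
    @property
    def seq_target_slice(self) -> slice:
        return slice(0, self.L_max)

    @property
    def ref_target_slice(self) -> slice:
        return slice(self.L_max, self.L_max + self.g2)

    @property
    def prot_target_slice(self) -> slice:
        return slice(self.L_max + self.g2, self.T)

    def prot_query_pos(self, j: int) -> int:
        """Input position whose output logits predict protein token j."""
        return self.L_max + self.g2 + j

    def segment_ids(self) -> np.ndarray:
        seg = np.empty(self.T, dtype=np.int64)
        seg[0] = 0
        seg[1:1 + self.L_max] = 1
        seg[1 + self.L_max:1 + self.L_max + self.g2] = 2
        seg[1 + self.L_max + self.g2:] = 3
        return seg


@dataclasses.dataclass
class TokenStream:
    """One assembled example: continuous inputs plus integer targets."""

    inputs: np.ndarray          # (T, width) embedded input stream
    seq_matrix: np.ndarray      # (L_max, width) raw frozen sequence embeddings
    seq_targets: np.ndarray     # (L_max,) residue ids (21-way; pad = X id)
    ref_targets: np.ndarray     # (g2,)
    prot_targets: np.ndarray    # (g2,)
    attention_mask: np.ndarray  # (T,) 1 where position is a real key
    seq_length: int


@dataclasses.dataclass
class ModelConfig:
    L_max: int = 100
    grid_edge: int = 8
    n_ref: int = 64
    n_prot: int = 64
    width: int = 96
    n_layers: int = 3
    n_heads: int = 4
    mlp_ratio: int = 2
    seq_loss_weight: float = 0.0
    ref_loss_weight: float = 1.0
    mask_padding: bool = True
    dropout: float = 0.1
    # train-time dropout of whole protein-prefix input positions: the class
    # identity is otherwise inferable from the teacher-forced prefix, which
    # starves the sequence pathway of gradient and mismatches generation,
    # where the model must commit to a localization before any prefix exists
    prot_input_dropout: float = 0.5
    steps: int = 900
    batch_size: int = 8
    lr: float = 3e-3
    weight_decay: float = 0.01
    grad_clip: float = 1.0
    warmup: int = 50
    early_stop_frac: float = 0.1   # train slice held out for early stopping
    eval_every: int = 100
    seed: int = 0

    @property
    def g2(self) -> int:
        return self.grid_edge ** 2

    @property
    def layout(self) -> StreamLayout:
        return StreamLayout(self.L_max, self.g2)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class Transformer:
    """Pre-LN causal transformer with per-vocabulary output heads."""

    def __init__(self, config: ModelConfig):
        if config.width % config.n_heads != 0:
            raise ValueError("width must be divisible by n_heads")
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.width

        def init(shape, scale=None):
            scale = scale if scale is not None else (2.0 / shape[0]) ** 0.5
            return Parameter(rng.normal(0, scale, size=shape))

        lay = config.layout
        self.start_vec = init((C,), 0.02)
        self.ref_embed = init((config.n_ref, C), 0.02)
        self.prot_embed = init((config.n_prot, C), 0.02)
        self.seq_pos_embed = init((config.L_max, C), 0.02)
        self.ref_pos_embed = init((config.g2, C), 0.02)
        self.prot_pos_embed = init((config.g2 - 1, C), 0.02)

        self.blocks = []
        h = config.mlp_ratio * C
        for _ in range(config.n_layers):
            blk = {
                "ln1_g": Parameter(np.ones(C)), "ln1_b": Parameter(np.zeros(C)),
                "w_qkv": init((C, 3 * C), C ** -0.5), "b_qkv": Parameter(np.zeros(3 * C)),
                "w_o": init((C, C), (C * config.n_layers) ** -0.5),
                "b_o": Parameter(np.zeros(C)),
                "ln2_g": Parameter(np.ones(C)), "ln2_b": Parameter(np.zeros(C)),
                "w_1": init((C, h)), "b_1": Parameter(np.zeros(h)),
                "w_2": init((h, C), (h * config.n_layers) ** -0.5),
                "b_2": Parameter(np.zeros(C)),
            }
            self.blocks.append(blk)
        self.lnf_g = Parameter(np.ones(C))
        self.lnf_b = Parameter(np.zeros(C))
        # zero-initialized heads: an untrained model emits uniform logits
        self.head_ref = Parameter(np.zeros((C, config.n_ref)))
        self.head_ref_b = Parameter(np.zeros(config.n_ref))
        self.head_prot = Parameter(np.zeros((C, config.n_prot)))
        self.head_prot_b = Parameter(np.zeros(config.n_prot))
        self.head_seq = Parameter(np.zeros((C, len(ALPHABET))))
        self.head_seq_b = Parameter(np.zeros(len(ALPHABET)))
        self._layout = lay

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[Parameter]:
        params = [self.start_vec, self.ref_embed, self.prot_embed,
                  self.seq_pos_embed, self.ref_pos_embed, self.prot_pos_embed,
                  self.lnf_g, self.lnf_b, self.head_ref, self.head_ref_b,
                  self.head_prot, self.head_prot_b, self.head_seq,
                  self.head_seq_b]
        for blk in self.blocks:
            params.extend(blk.values())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {"start_vec": self.start_vec.data, "ref_embed": self.ref_embed.data,
                 "prot_embed": self.prot_embed.data,
                 "seq_pos_embed": self.seq_pos_embed.data,
                 "ref_pos_embed": self.ref_pos_embed.data,
                 "prot_pos_embed": self.prot_pos_embed.data,
                 "lnf_g": self.lnf_g.data, "lnf_b": self.lnf_b.data,
                 "head_ref": self.head_ref.data, "head_ref_b": self.head_ref_b.data,
                 "head_prot": self.head_prot.data,
                 "head_prot_b": self.head_prot_b.data,
                 "head_seq": self.head_seq.data, "head_seq_b": self.head_seq_b.data}
        for i, blk in enumerate(self.blocks):
            for k, v in blk.items():
                state[f"blk{i}_{k}"] = v.data
        return state

    def save(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.state_arrays().items()}
        payload["_config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "Transformer":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["_config_json"]).decode()))
            model = cls(cfg)
            state = model.state_arrays()
            for k in state:
                state[k][...] = data[k]
        return model

    # -- stream assembly --------------------------------------------------
    def assemble_stream(self, seq_embedding: SequenceEmbedding,
                        ref_grid: TokenGrid,
                        prot_grid: TokenGrid | None = None,
                        materialize: bool = True) -> TokenStream:
        """Build the embedded input stream and shift-by-one targets.

        ``prot_grid`` may be omitted at inference; the protein segment is
        then left zeroed (generation fills it incrementally).
        ``materialize=False`` skips the embedded-input array (training
        re-embeds inside the autodiff graph anyway), which keeps large
        augmented stream sets cheap to hold in memory.
        """
        cfg = self.config
        lay = self._layout
        if seq_embedding.matrix.shape != (cfg.L_max, cfg.width):
            raise ValueError(
                f"sequence embedding shape {seq_embedding.matrix.shape} does not "
                f"match (L_max={cfg.L_max}, width={cfg.width})")
        if ref_grid.g != cfg.grid_edge:
            raise ValueError("reference grid size mismatch with model config")
        ref_flat = ref_grid.flatten()
        prot_targets = np.zeros(cfg.g2, dtype=np.int64)
        if prot_grid is not None:
            if prot_grid.g != cfg.grid_edge:
                raise ValueError("protein grid size mismatch with model config")
            prot_targets = prot_grid.flatten()
        if materialize:
            inputs = np.zeros((lay.T, cfg.width))
            inputs[0] = self.start_vec.data
            inputs[1:1 + cfg.L_max] = (seq_embedding.matrix
                                       + self.seq_pos_embed.data)
            inputs[1 + cfg.L_max:1 + cfg.L_max + cfg.g2] = (
                self.ref_embed.data[ref_flat] + self.ref_pos_embed.data)
            if prot_grid is not None:
                inputs[1 + cfg.L_max + cfg.g2:] = (
                    self.prot_embed.data[prot_targets[:-1]]
                    + self.prot_pos_embed.data)
        else:
            inputs = np.empty((0, 0))
        mask = np.ones(lay.T)
        if cfg.mask_padding:
            mask[1 + seq_embedding.length:1 + cfg.L_max] = 0.0
        seq_ids = np.full(cfg.L_max, ALPHABET.index("X"), dtype=np.int64)
        return TokenStream(inputs=inputs, seq_matrix=seq_embedding.matrix,
                           seq_targets=seq_ids,
                           ref_targets=ref_flat.astype(np.int64),
                           prot_targets=prot_targets,
                           attention_mask=mask, seq_length=seq_embedding.length)

    def _attn_bias(self, key_masks: np.ndarray) -> np.ndarray:
        """(B, 1, T, T) additive bias: causal plus padded-key masking."""
        T = self._layout.T
        causal = np.triu(np.ones((T, T)), k=1)
        bias = causal[None, None] * -1e9
        pad = (1.0 - key_masks)[:, None, None, :] * -1e9
        bias = bias + pad
        return bias

    # -- differentiable forward (training) --------------------------------
    def _embed_batch_graph(self, streams: list[TokenStream],
                           drop_rng: np.random.Generator | None = None) -> Tensor:
        """Re-assemble inputs inside the autodiff graph for a batch."""
        cfg = self.config
        B = len(streams)
        seq_const = ad.constant(np.stack([s.seq_matrix for s in streams]))
        seq_part = seq_const + self.seq_pos_embed.reshape(1, cfg.L_max, cfg.width)
        ref_idx = np.stack([s.ref_targets for s in streams])
        ref_part = (self.ref_embed.take_rows(ref_idx)
                    + self.ref_pos_embed.reshape(1, cfg.g2, cfg.width))
        prot_idx = np.stack([s.prot_targets[:-1] for s in streams])
        prot_part = (self.prot_embed.take_rows(prot_idx)
                     + self.prot_pos_embed.reshape(1, cfg.g2 - 1, cfg.width))
        if drop_rng is not None and cfg.prot_input_dropout > 0:
            keep = (drop_rng.random((B, cfg.g2 - 1, 1))
                    >= cfg.prot_input_dropout).astype(np.float64)
            prot_part = prot_part * ad.constant(keep)
        start = self.start_vec.reshape(1, 1, cfg.width) + ad.constant(
            np.zeros((B, 1, cfg.width)))
        return ad.concat([start, seq_part, ref_part, prot_part], axis=1)

    def _forward_graph(self, x: Tensor, key_masks: np.ndarray,
                       drop_rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        B, T, C = x.shape
        H = cfg.n_heads
        hd = C // H
        bias = ad.constant(self._attn_bias(key_masks))

        def dropout(t: Tensor) -> Tensor:
            if drop_rng is None or cfg.dropout <= 0:
                return t
            keep = (drop_rng.random(t.shape) >= cfg.dropout) / (1 - cfg.dropout)
            return t * ad.constant(keep)

        for blk in self.blocks:
            normed = ad.layer_norm(x, blk["ln1_g"], blk["ln1_b"])
            qkv = normed @ blk["w_qkv"] + blk["b_qkv"]
            q = qkv[:, :, :C].reshape(B, T, H, hd).swapaxes(1, 2)
            k = qkv[:, :, C:2 * C].reshape(B, T, H, hd).swapaxes(1, 2)
            v = qkv[:, :, 2 * C:].reshape(B, T, H, hd).swapaxes(1, 2)
            scores = (q @ k.swapaxes(2, 3)) * (hd ** -0.5) + bias
            attn = ad.softmax(scores, axis=-1)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, C)
            x = x + dropout(ctx @ blk["w_o"] + blk["b_o"])
            normed2 = ad.layer_norm(x, blk["ln2_g"], blk["ln2_b"])
            x = x + dropout((normed2 @ blk["w_1"] + blk["b_1"]).relu()
                            @ blk["w_2"] + blk["b_2"])
        return ad.layer_norm(x, self.lnf_g, self.lnf_b)

    def loss(self, streams: list[TokenStream],
             drop_rng: np.random.Generator | None = None,
             ) -> tuple[Tensor, dict[str, float]]:
        cfg = self.config
        lay = self._layout
        x = self._embed_batch_graph(streams, drop_rng=drop_rng)
        key_masks = np.stack([s.attention_mask for s in streams])
        h = self._forward_graph(x, key_masks, drop_rng=drop_rng)

        prot_h = h[:, lay.prot_target_slice, :]
        prot_logits = prot_h @ self.head_prot + self.head_prot_b
        prot_targets = np.stack([s.prot_targets for s in streams])
        loss_prot = ad.cross_entropy_logits(prot_logits, prot_targets)
        total = loss_prot
        parts = {"prot_ce": float(loss_prot.data)}

        if cfg.ref_loss_weight > 0:
            ref_h = h[:, lay.ref_target_slice, :]
            ref_logits = ref_h @ self.head_ref + self.head_ref_b
            ref_targets = np.stack([s.ref_targets for s in streams])
            loss_ref = ad.cross_entropy_logits(ref_logits, ref_targets)
            total = total + cfg.ref_loss_weight * loss_ref
            parts["ref_ce"] = float(loss_ref.data)
        if cfg.seq_loss_weight > 0:
            seq_h = h[:, lay.seq_target_slice, :]
            seq_logits = seq_h @ self.head_seq + self.head_seq_b
            seq_targets = np.stack([s.seq_targets for s in streams])
            weights = np.stack([s.attention_mask[1:1 + cfg.L_max] for s in streams])
            loss_seq = ad.cross_entropy_logits(seq_logits, seq_targets,
                                               weights=weights)
            total = total + cfg.seq_loss_weight * loss_seq
            parts["seq_ce"] = float(loss_seq.data)
        parts["total"] = float(total.data)
        return total, parts

    # -- numpy forward (inference) -----------------------------------------
    def _np_params(self):
        return self.state_arrays()

    def forward(self, stream: TokenStream, capture_attention: bool = False):
        """Teacher-forced forward pass on one stream (no gradients).

        Returns ``(ref_logits, prot_logits)`` with shapes (g2, n_ref) and
        (g2, n_prot); with ``capture_attention`` also an AttentionRecord
        array of shape (layers, heads, T, T) of row-stochastic weights.
        """
        cfg = self.config
        lay = self._layout
        x = stream.inputs.copy()
        bias = self._attn_bias(stream.attention_mask[None])[0, 0]
        H, C = cfg.n_heads, cfg.width
        hd = C // H
        records = []
        for blk in self.blocks:
            normed = _ln(x, blk["ln1_g"].data, blk["ln1_b"].data)
            qkv = normed @ blk["w_qkv"].data + blk["b_qkv"].data
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(-1, H, hd).transpose(1, 0, 2)
            k = k.reshape(-1, H, hd).transpose(1, 0, 2)
            v = v.reshape(-1, H, hd).transpose(1, 0, 2)
            scores = q @ k.transpose(0, 2, 1) * hd ** -0.5 + bias[None]
            attn = _softmax_np(scores)
            if capture_attention:
                records.append(attn)
            ctx = (attn @ v).transpose(1, 0, 2).reshape(-1, C)
            x = x + ctx @ blk["w_o"].data + blk["b_o"].data
            normed2 = _ln(x, blk["ln2_g"].data, blk["ln2_b"].data)
            x = x + np.maximum(normed2 @ blk["w_1"].data + blk["b_1"].data, 0.0) \
                @ blk["w_2"].data + blk["b_2"].data
        h = _ln(x, self.lnf_g.data, self.lnf_b.data)
        if not np.isfinite(h).all():
            raise FloatingPointError("non-finite activations in forward pass")
        ref_logits = h[lay.ref_target_slice] @ self.head_ref.data + self.head_ref_b.data
        prot_logits = (h[lay.prot_target_slice] @ self.head_prot.data
                       + self.head_prot_b.data)
        if capture_attention:
            return ref_logits, prot_logits, np.stack(records)
        return ref_logits, prot_logits

    # -- incremental decode -------------------------------------------------
    def init_cache(self, stream_prefix: np.ndarray, prefix_mask: np.ndarray):
        """Process the [start | sequence | reference] prefix; return a KV cache.

        The returned cache state exposes ``append(vec) -> hidden`` to extend
        the stream one embedded position at a time.
        """
        return _DecodeCache(self, stream_prefix, prefix_mask)

    def prot_logits_from_hidden(self, hidden: np.ndarray) -> np.ndarray:
        return hidden @ self.head_prot.data + self.head_prot_b.data

    def prot_input_vector(self, token: int, position: int) -> np.ndarray:
        """Embedded input for protein token ``token`` at grid position."""
        return self.prot_embed.data[token] + self.prot_pos_embed.data[position]

    def joint_log_likelihood(self, stream: TokenStream) -> tuple[float, np.ndarray]:
        """Joint log-likelihood of the image tokens of a stream.

        Returns the total and the per-position log-probabilities
        (reference tokens first, then protein tokens).
        """
        ref_logits, prot_logits = self.forward(stream)
        ref_lp = _log_softmax_np(ref_logits)[
            np.arange(self.config.g2), stream.ref_targets]
        prot_lp = _log_softmax_np(prot_logits)[
            np.arange(self.config.g2), stream.prot_targets]
        per_pos = np.concatenate([ref_lp, prot_lp])
        return float(per_pos.sum()), per_pos

    def checksum(self) -> str:
        m = hashlib.sha256()
        for k in sorted(self.state_arrays()):
            m.update(np.ascontiguousarray(self.state_arrays()[k]).tobytes())
        return m.hexdigest()


class _DecodeCache:
    """Per-layer key/value cache for incremental autoregressive decoding."""

    def __init__(self, model: Transformer, prefix: np.ndarray,
                 prefix_mask: np.ndarray):
        self.model = model
        cfg = model.config
        self.H = cfg.n_heads
        self.hd = cfg.width // self.H
        self.keys = [None] * cfg.n_layers
        self.values = [None] * cfg.n_layers
        self.key_masks = np.zeros(0)
        self.length = 0
        self._hidden_last: np.ndarray | None = None
        prefix_mask = np.asarray(prefix_mask, dtype=np.float64)
        for t in range(prefix.shape[0]):
            self.append(prefix[t], prefix_mask[t])

    def append(self, vec: np.ndarray, key_mask: float = 1.0) -> np.ndarray:
        """Extend the stream by one embedded position; return its hidden state."""
        m = self.model
        self.key_masks = np.append(self.key_masks, key_mask)
        x = vec.copy()
        for i, blk in enumerate(m.blocks):
            normed = _ln(x, blk["ln1_g"].data, blk["ln1_b"].data)
            qkv = normed @ blk["w_qkv"].data + blk["b_qkv"].data
            q, k, v = np.split(qkv, 3)
            q = q.reshape(self.H, self.hd)
            k = k.reshape(self.H, 1, self.hd)
            v = v.reshape(self.H, 1, self.hd)
            if self.keys[i] is None:
                self.keys[i], self.values[i] = k, v
            else:
                self.keys[i] = np.concatenate([self.keys[i], k], axis=1)
                self.values[i] = np.concatenate([self.values[i], v], axis=1)
            scores = np.einsum("hd,htd->ht", q, self.keys[i]) * self.hd ** -0.5
            scores = scores + (1.0 - self.key_masks)[None, :] * -1e9
            attn = _softmax_np(scores)
            ctx = np.einsum("ht,htd->hd", attn, self.values[i]).reshape(-1)
            x = x + ctx @ blk["w_o"].data + blk["b_o"].data
            normed2 = _ln(x, blk["ln2_g"].data, blk["ln2_b"].data)
            x = x + np.maximum(normed2 @ blk["w_1"].data + blk["b_1"].data, 0.0) \
                @ blk["w_2"].data + blk["b_2"].data
        self.length += 1
        self._hidden_last = _ln(x, m.lnf_g.data, m.lnf_b.data)
        return self._hidden_last


def _ln(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def _gelu(x: np.ndarray) -> np.ndarray:
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x ** 3)))


def _softmax_np(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _log_softmax_np(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))


def provider_checksum(provider) -> str:
    """Checksum of a frozen embedding provider's lookup content."""
    m = hashlib.sha256()
    if hasattr(provider, "table"):
        for ch in sorted(provider.table):
            m.update(ch.encode())
            m.update(np.ascontiguousarray(provider.table[ch]).tobytes())
        if hasattr(provider, "offset_proj"):
            m.update(np.ascontiguousarray(provider.offset_proj).tobytes())
    elif hasattr(provider, "matrices"):
        for k in sorted(provider.matrices):
            m.update(k.encode())
            m.update(np.ascontiguousarray(provider.matrices[k]).tobytes())
    return m.hexdigest()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_transformer(streams: list[TokenStream], config: ModelConfig,
                      frozen_checksums: dict[str, str] | None = None,
                      recheck: dict[str, callable] | None = None,
                      log_path: str | Path | None = None,
                      model: Transformer | None = None,
                      holdout_streams: list[TokenStream] | None = None,
                      ) -> tuple[Transformer, list[dict[str, float]]]:
    """Train the token prior on pre-assembled streams.

    Early stopping tracks protein-token cross-entropy on a holdout set
    (``holdout_streams`` if given, else a random ``early_stop_frac`` slice
    of ``streams``) and restores the best parameters at the end.
    ``frozen_checksums``/``recheck`` let callers register the codec and
    embedding-provider checksums; they are verified after training so any
    accidental mutation of a frozen component aborts loudly.
    """
    model = model or Transformer(config)
    rng = np.random.default_rng(config.seed + 7)
    drop_rng = np.random.default_rng(config.seed + 13)
    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)

    if holdout_streams is not None:
        holdout = list(holdout_streams)
        pool = list(streams)
    else:
        n_hold = int(round(config.early_stop_frac * len(streams)))
        hold_idx = rng.choice(len(streams), size=n_hold, replace=False) \
            if n_hold >= 2 else np.array([], dtype=int)
        holdout = [streams[i] for i in hold_idx]
        pool = [s for i, s in enumerate(streams)
                if i not in set(hold_idx.tolist())]

    best_ce = np.inf
    best_state: dict[str, np.ndarray] | None = None
    history: list[dict[str, float]] = []
    rows = ["step,lr,total,prot_ce,holdout_ce"]

    def holdout_ce() -> float:
        _, parts = model.loss(holdout)
        return parts["prot_ce"]

    for step in range(config.steps):
        idx = rng.choice(len(pool), size=min(config.batch_size, len(pool)),
                         replace=False)
        batch = [pool[i] for i in idx]
        loss, parts = model.loss(batch, drop_rng=drop_rng)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite training loss at step {step}")
        opt.zero_grad()
        loss.backward()
        ad.clip_global_norm(model.parameters(), config.grad_clip)
        lr = ad.cosine_lr(step, config.steps, config.lr, warmup=config.warmup)
        opt.step(lr=lr)
        parts["step"] = step
        parts["lr"] = lr
        if holdout and (step + 1) % config.eval_every == 0:
            ce = holdout_ce()
            parts["holdout_ce"] = ce
            if ce < best_ce:
                best_ce = ce
                best_state = {k: v.copy()
                              for k, v in model.state_arrays().items()}
        history.append(parts)
        rows.append(f"{step},{lr:.6g},{parts['total']:.6f},"
                    f"{parts['prot_ce']:.6f},{parts.get('holdout_ce', '')}")
    if best_state is not None:
        state = model.state_arrays()
        for k in state:
            state[k][...] = best_state[k]
    if frozen_checksums and recheck:
        for name, fn in recheck.items():
            after = fn()
            if after != frozen_checksums.get(name):
                raise RuntimeError(
                    f"frozen component '{name}' changed during training")
    if log_path is not None:
        Path(log_path).write_text("\n".join(rows) + "\n")
    return model, history
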