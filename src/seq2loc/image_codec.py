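"""Vector-quantized image tokenizers for the reference and protein channels.

Two codecs share one implementation: each non-overlapping ``p x p`` patch is
mapped by a small encoder network to a ``d``-dimensional latent, snapped to
the nearest vector of a learned codebook (EMA-updated, with dead-code
re-seeding), and decoded back to a patch.  An image therefore becomes a
``g x g`` grid of codebook indices with ``g = image_edge / patch_edge``.

The protein channel is tokenized after mean-threshold binarization: each
pixel becomes 1 iff it is at least the image mean, turning the channel into
a discrete spatial distribution of protein presence.  The binary-channel
codec reconstructs per-pixel probabilities through a sigmoid and trains with
binary cross-entropy; the grayscale reference codec trains with L1.  An
optional patch-level discriminator supplies an adversarial term
(weight 0 by default at mini scale).
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import AdamW, Parameter, Tensor

__all__ = [
    "Codebook", "TokenGrid", "CodecConfig", "VQCodec",
    "binarize", "quantize", "train_codec",
]


# ---------------------------------------------------------------------------
# binarization (mean threshold)
# ---------------------------------------------------------------------------


def binarize(image: np.ndarray) -> np.ndarray:
    """Mean-threshold an intensity image to {0, 1}.

    A pixel maps to 1 iff it is >= the image mean (inclusive), so a
    constant image maps to all ones.  Idempotent.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    out = image >= image.mean()
    if not out.any():
        # the true mean never exceeds the max, so an empty result can only
        # be accumulation rounding (e.g. a constant image); fall back to
        # the exact-max pixels, which satisfy u >= mu mathematically
        out = image == image.max()
    return out.astype(np.float64)


# ---------------------------------------------------------------------------
# codebook and token grids
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Codebook:
    """Ordered set of ``n`` latent vectors of dimension ``d``."""

    vectors: np.ndarray  # (n, d)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 2:
            raise ValueError("codebook needs at least 2 vectors (n x d array)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("codebook vectors must be finite")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclasses.dataclass
class TokenGrid:
    """g x g grid of codebook indices, row-major from the top-left."""

    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2 or self.indices.shape[0] != self.indices.shape[1]:
            raise ValueError("token grid must be square")

    @property
    def g(self) -> int:
        return self.indices.shape[0]

    def flatten(self) -> np.ndarray:
        return self.indices.reshape(-1)


def quantize(latent_vector: np.ndarray, codebook: Codebook) -> int:
    """Index of the nearest codebook vector (Euclidean; ties -> lowest index)."""
    v = np.asarray(latent_vector, dtype=np.float64)
    if v.shape != (codebook.d,):
        raise ValueError(f"latent dimension {v.shape} != codebook d={codebook.d}")
    dists = ((codebook.vectors - v) ** 2).sum(axis=1)
    return int(np.argmin(dists))  # argmin returns the first (lowest) minimizer


def _quantize_batch(latents: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    d2 = ((latents[:, None, :] - vectors[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# codec model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CodecConfig:
    patch_edge: int = 8
    n_codes: int = 64
    latent_dim: int = 32
    hidden: int = 128
    channel: str = "threshold"        # "reference" (L1) or "threshold" (BCE)
    commitment_beta: float = 0.25
    adversarial_weight: float = 0.0   # patch-discriminator loss weight
    ema_decay: float = 0.9
    epochs: int = 50
    batch_size: int = 512
    lr: float = 2e-3
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class VQCodec:
    """Patch-wise VQ autoencoder: image <-> TokenGrid."""

    def __init__(self, config: CodecConfig):
        self.config = config
        p2 = config.patch_edge ** 2
        rng = np.random.default_rng(config.seed)

        def init(shape, scale):
            return Parameter(rng.normal(0, scale, size=shape))

        h, d = config.hidden, config.latent_dim
        self.enc_w1 = init((p2, h), (2.0 / p2) ** 0.5)
        self.enc_b1 = Parameter(np.zeros(h))
        self.enc_w2 = init((h, d), (2.0 / h) ** 0.5)
        self.enc_b2 = Parameter(np.zeros(d))
        self.dec_w1 = init((d, h), (2.0 / d) ** 0.5)
        self.dec_b1 = Parameter(np.zeros(h))
        self.dec_w2 = init((h, p2), (2.0 / h) ** 0.5)
        self.dec_b2 = Parameter(np.zeros(p2))
        # codebook initialized broadly; EMA stats updated during training
        self.codebook_vectors = rng.normal(0, 1.0, size=(config.n_codes, d))
        self._ema_count = np.ones(config.n_codes)
        self._ema_sum = self.codebook_vectors * self._ema_count[:, None]
        self.trained = False
        # patch discriminator (logistic MLP); only trained if weight > 0
        self.disc_w1 = init((p2, h), (2.0 / p2) ** 0.5)
        self.disc_b1 = Parameter(np.zeros(h))
        self.disc_w2 = init((h, 1), (2.0 / h) ** 0.5)
        self.disc_b2 = Parameter(np.zeros(1))

    # -- helpers --------------------------------------------------------
    @property
    def codebook(self) -> Codebook:
        return Codebook(self.codebook_vectors.copy())

    def parameters(self) -> list[Parameter]:
        return [self.enc_w1, self.enc_b1, self.enc_w2, self.enc_b2,
                self.dec_w1, self.dec_b1, self.dec_w2, self.dec_b2]

    def _check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        p = self.config.patch_edge
        if image.ndim != 2 or image.shape[0] != image.shape[1]:
            raise ValueError("expected a square 2-D image")
        if image.shape[0] % p != 0:
            raise ValueError(f"image edge {image.shape[0]} not divisible by "
                             f"patch edge {p}")
        return image

    def patchify(self, image: np.ndarray) -> np.ndarray:
        """(H, W) -> (g*g, p*p) flattened patches, row-major grid order."""
        image = self._check_image(image)
        p = self.config.patch_edge
        g = image.shape[0] // p
        patches = image.reshape(g, p, g, p).transpose(0, 2, 1, 3)
        return patches.reshape(g * g, p * p)

    def unpatchify(self, patches: np.ndarray, g: int) -> np.ndarray:
        p = self.config.patch_edge
        return (patches.reshape(g, g, p, p).transpose(0, 2, 1, 3)
                .reshape(g * p, g * p))

    # -- encoder / decoder ----------------------------------------------
    def _encode_latents(self, patches: np.ndarray) -> np.ndarray:
        h = np.maximum(patches @ self.enc_w1.data + self.enc_b1.data, 0.0)
        return h @ self.enc_w2.data + self.enc_b2.data

    def _decode_patches_np(self, latents: np.ndarray) -> np.ndarray:
        h = np.maximum(latents @ self.dec_w1.data + self.dec_b1.data, 0.0)
        logits = np.clip(h @ self.dec_w2.data + self.dec_b2.data, -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(-logits))

    def encode(self, image: np.ndarray) -> TokenGrid:
        """Quantize an image to its g x g grid of nearest-codebook indices."""
        patches = self.patchify(image)
        latents = self._encode_latents(patches)
        idx = _quantize_batch(latents, self.codebook_vectors)
        g = image.shape[0] // self.config.patch_edge
        return TokenGrid(idx.reshape(g, g))

    def decode(self, grid: TokenGrid) -> np.ndarray:
        """Decode a token grid to an image with pixel values in [0, 1]."""
        idx = grid.flatten()
        if idx.min() < 0 or idx.max() >= self.config.n_codes:
            raise ValueError("token index out of codebook range")
        latents = self.codebook_vectors[idx]
        return self.decode_latents(latents, grid.g)

    def decode_latents(self, latents: np.ndarray, g: int) -> np.ndarray:
        """Decode a (g*g, d) latent grid (not necessarily on-codebook)."""
        patches = self._decode_patches_np(np.asarray(latents, dtype=np.float64))
        return np.clip(self.unpatchify(patches, g), 0.0, 1.0)

    # -- training ---------------------------------------------------------
    def _recon_loss(self, patch_logits: Tensor, targets: np.ndarray) -> Tensor:
        if self.config.channel == "threshold":
            # BCE on sigmoid(logits) against binary targets, in logit form
            t = ad.constant(targets)
            # log(1+exp(x)) stable via softplus decomposition
            probs = patch_logits.sigmoid()
            eps = 1e-7
            probs = probs * (1 - 2 * eps) + eps
            return -(t * probs.log() + (1.0 - t) * (1.0 - probs).log()).mean()
        diff = patch_logits.sigmoid() - ad.constant(targets)
        return ((diff ** 2.0 + 1e-8) ** 0.5).mean()   # smooth L1 surrogate

    def _forward_train(self, patches: np.ndarray):
        x = ad.constant(patches)
        h = (x @ self.enc_w1 + self.enc_b1).relu()
        z_e = h @ self.enc_w2 + self.enc_b2
        idx = _quantize_batch(z_e.data, self.codebook_vectors)
        e = self.codebook_vectors[idx]
        # straight-through: decoder sees e, encoder gradient passes through
        z_q = z_e + ad.constant(e - z_e.data)
        hd = (z_q @ self.dec_w1 + self.dec_b1).relu()
        logits = hd @ self.dec_w2 + self.dec_b2
        commit = ((z_e - ad.constant(e)) ** 2.0).mean()
        return logits, commit, idx, z_e.data

    def _ema_update(self, idx: np.ndarray, latents: np.ndarray) -> None:
        decay = self.config.ema_decay
        n = self.config.n_codes
        counts = np.bincount(idx, minlength=n).astype(np.float64)
        sums = np.zeros_like(self._ema_sum)
        np.add.at(sums, idx, latents)
        self._ema_count = decay * self._ema_count + (1 - decay) * counts
        self._ema_sum = decay * self._ema_sum + (1 - decay) * sums
        active = self._ema_count > 1e-3
        self.codebook_vectors[active] = (self._ema_sum[active]
                                         / self._ema_count[active][:, None])

    def _reseed_dead_codes(self, latents: np.ndarray,
                           rng: np.random.Generator) -> None:
        dead = self._ema_count < 1e-3
        n_dead = int(dead.sum())
        if n_dead and len(latents):
            picks = rng.choice(len(latents), size=n_dead, replace=True)
            self.codebook_vectors[dead] = latents[picks]
            self._ema_count[dead] = 1.0
            self._ema_sum[dead] = self.codebook_vectors[dead]

    def fit(self, images: list[np.ndarray],
            log_path: str | Path | None = None) -> list[float]:
        """Train on a list of images; returns the per-epoch loss curve."""
        cfg = self.config
        if len(images) < 16:
            raise ValueError("need at least 16 training images")
        all_patches = np.concatenate([self.patchify(im) for im in images])
        rng = np.random.default_rng(cfg.seed + 1)
        opt = AdamW(self.parameters(), lr=cfg.lr, weight_decay=1e-5)
        disc_opt = AdamW([self.disc_w1, self.disc_b1, self.disc_w2, self.disc_b2],
                         lr=cfg.lr)
        curve: list[float] = []
        rows: list[str] = ["epoch,loss"]
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(all_patches))
            epoch_losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = all_patches[order[start:start + cfg.batch_size]]
                logits, commit, idx, z_e = self._forward_train(batch)
                loss = self._recon_loss(logits, batch) + cfg.commitment_beta * commit
                if cfg.adversarial_weight > 0:
                    loss = loss + cfg.adversarial_weight * self._gen_adv_loss(logits)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite codec loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                ad.clip_global_norm(self.parameters(), 5.0)
                opt.step()
                self._ema_update(idx, z_e)
                if cfg.adversarial_weight > 0:
                    self._disc_step(batch, logits.data, disc_opt)
                epoch_losses.append(float(loss.data))
            self._reseed_dead_codes(z_e, rng)
            curve.append(float(np.mean(epoch_losses)))
            rows.append(f"{epoch},{curve[-1]:.6f}")
        if log_path is not None:
            Path(log_path).write_text("\n".join(rows) + "\n")
        self.calibrate()
        self.trained = True
        return curve

    def calibrate(self, iterations: int = 15) -> int:
        """Make the codebook round-trip consistent: encode(decode(T)) == T.

        Each code is pulled toward the fixed point of encode-of-decode,
        then any code whose canonical patch still re-encodes elsewhere is
        snapped onto its nearest self-consistent code.  Duplicated codes
        are harmless: they decode identically and quantization ties break
        to the lowest index.  Returns the number of codes snapped.
        """
        W = self.codebook_vectors
        for _ in range(iterations):
            W = self._encode_latents(self._decode_patches_np(W))
        Z = self._encode_latents(self._decode_patches_np(W))
        idx = _quantize_batch(Z, W)
        consistent = idx == np.arange(len(W))
        n_bad = int((~consistent).sum())
        if consistent.any() and n_bad:
            keep = W[consistent]
            for i in np.flatnonzero(~consistent):
                d = ((keep - Z[i]) ** 2).sum(axis=1)
                W[i] = keep[d.argmin()]
        self.codebook_vectors = W
        return n_bad

    # -- adversarial term (optional) --------------------------------------
    def _disc_logits(self, patches) -> Tensor:
        x = patches if isinstance(patches, Tensor) else ad.constant(patches)
        h = (x @ self.disc_w1 + self.disc_b1).relu()
        return h @ self.disc_w2 + self.disc_b2

    def _gen_adv_loss(self, patch_logits: Tensor) -> Tensor:
        # generator wants reconstructions classified as real
        fake = patch_logits.sigmoid()
        s = self._disc_logits(fake).sigmoid()
        return -((s * (1 - 2e-7) + 1e-7).log()).mean()

    def _disc_step(self, real: np.ndarray, fake_logits: np.ndarray,
                   opt: AdamW) -> None:
        fake = 1.0 / (1.0 + np.exp(-fake_logits))
        sr = self._disc_logits(real).sigmoid()
        sf = self._disc_logits(fake).sigmoid()
        eps = 1e-7
        loss = (-((sr * (1 - 2 * eps) + eps).log()).mean()
                - ((1.0 - sf * (1 - 2 * eps) - eps).log()).mean())
        opt.zero_grad()
        loss.backward()
        opt.step()

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        names = ["enc_w1", "enc_b1", "enc_w2", "enc_b2",
                 "dec_w1", "dec_b1", "dec_w2", "dec_b2"]
        state = {name: getattr(self, name).data for name in names}
        state["codebook_vectors"] = self.codebook_vectors
        return state

    def save(self, path: str | Path) -> None:
        payload = dict(self.state_arrays())
        payload["_config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        payload["_trained"] = np.array([int(self.trained)])
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "VQCodec":
        with np.load(path) as data:
            cfg = CodecConfig(**json.loads(bytes(data["_config_json"]).decode()))
            codec = cls(cfg)
            for name in ["enc_w1", "enc_b1", "enc_w2", "enc_b2",
                         "dec_w1", "dec_b1", "dec_w2", "dec_b2"]:
                getattr(codec, name).data = data[name].copy()
            codec.codebook_vectors = data["codebook_vectors"].copy()
            codec.trained = bool(data["_trained"][0])
        return codec

    def checksum(self) -> str:
        buf = io.BytesIO()
        for k in sorted(self.state_arrays()):
            buf.write(np.ascontiguousarray(self.state_arrays()[k]).tobytes())
        import hashlib
        return hashlib.sha256(buf.getvalue()).hexdigest()


def train_codec(images: list[np.ndarray], channel: str,
                config: CodecConfig | None = None,
                log_path: str | Path | None = None) -> tuple[VQCodec, list[float]]:
    """Train a codec for one channel; images for 'threshold' are binarized."""
    config = config or CodecConfig()
    config = dataclasses.replace(config, channel=channel)
    if channel == "threshold":
        images = [binarize(im) for im in images]
    elif channel != "reference":
        raise ValueError("channel must be 'reference' or 'threshold'")
    codec = VQCodec(config)
    curve = codec.fit(images, log_path=log_path)
    return codec, curve
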