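"""Autoregressive generation and probability-density-map construction.

Given an amino-acid sequence and a reference nucleus image, the trained
transformer fills the protein-threshold token grid position by position.
Each token is drawn by restricting the logits to the top quartile of
codebook entries (by logit rank), optionally truncating further to the k
best, and taking the Gumbel-noise argmax over the retained set — which
samples exactly from the softmax of the retained logits.

The per-position pre-sampling logits also yield a continuous probability
density map: per grid position the softmax probabilities p(v_i) are
clipped to [0, 1] and used as weights in a convex combination
sum_i w_i p(v_i) of the codebook vectors w_i.  The resulting latent grid
is decoded once through the threshold codec's decoder and peak-normalized,
giving a per-pixel relative-confidence image over the reference frame.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .core_transformer import Transformer, _softmax_np
from .image_codec import TokenGrid, VQCodec, binarize
from .sequence_embed import SequenceEmbedding, embed

__all__ = ["sample_token", "generate_tokens", "build_probability_map",
           "predict", "ProbabilityMap", "ModelBundle"]


@dataclasses.dataclass
class ProbabilityMap:
    """Per-pixel relative-confidence image in [0, 1]."""

    pixels: np.ndarray
    normalization: str  # "peak", "mass", or "none" (all-zero map)

    def __post_init__(self):
        if (self.pixels < -1e-9).any() or (self.pixels > 1 + 1e-9).any():
            raise ValueError("probability map pixels must lie in [0, 1]")


def sample_token(logits: np.ndarray, rng: np.random.Generator,
                 quartile: float = 0.25, k: int | None = None) -> int:
    """Sample a codebook index from truncated logits with Gumbel noise.

    The ``ceil(n * quartile)`` highest-logit entries are retained (ties at
    the cut broken toward the lower index), optionally narrowed to the top
    ``k`` of those; standard Gumbel noise is added to the retained logits
    and the argmax returned.  Indices outside the retained set have
    sampling probability exactly zero.
    """
    logits = np.asarray(logits, dtype=np.float64)
    n = logits.shape[0]
    if n < 4:
        raise ValueError("need at least 4 codebook entries to take a quartile")
    keep = math.ceil(n * quartile)
    # stable sort on -logits: equal logits keep ascending index order
    order = np.argsort(-logits, kind="stable")
    retained = order[:keep]
    if k is not None:
        retained = retained[:max(1, min(k, keep))]
    noise = rng.gumbel(size=retained.shape[0])
    return int(retained[np.argmax(logits[retained] + noise)])


def generate_tokens(model: Transformer, seq_embedding: SequenceEmbedding,
                    ref_grid: TokenGrid, rng: np.random.Generator,
                    quartile: float = 0.25, k: int | None = None,
                    ) -> tuple[TokenGrid, np.ndarray]:
    """Fill the protein token grid row-major from the top-left.

    Returns the sampled grid and the pre-sampling logits recorded at every
    position, shape (g^2, n_prot).  The logits at position j are computed
    before token j is appended to the stream.
    """
    cfg = model.config
    if ref_grid.g != cfg.grid_edge:
        raise ValueError("reference grid does not match the model configuration")
    stream = model.assemble_stream(seq_embedding, ref_grid)
    prefix_len = 1 + cfg.L_max + cfg.g2
    cache = model.init_cache(stream.inputs[:prefix_len],
                             stream.attention_mask[:prefix_len])
    hidden = cache._hidden_last  # hidden of the last reference position
    tokens = np.empty(cfg.g2, dtype=np.int64)
    all_logits = np.empty((cfg.g2, cfg.n_prot))
    for j in range(cfg.g2):
        logits = model.prot_logits_from_hidden(hidden)
        all_logits[j] = logits
        tokens[j] = sample_token(logits, rng, quartile=quartile, k=k)
        if j < cfg.g2 - 1:
            hidden = cache.append(model.prot_input_vector(tokens[j], j))
    g = cfg.grid_edge
    return TokenGrid(tokens.reshape(g, g)), all_logits


def build_probability_map(token_logits: np.ndarray, codec: VQCodec,
                          mode: str = "latent",
                          normalization: str = "peak") -> ProbabilityMap:
    """Decode per-position token probabilities into a probability map.

    ``mode='latent'`` (default) forms the probability-weighted convex
    combination of codebook vectors per grid position and decodes the
    latent grid once; ``mode='pixel'`` instead decodes every codebook entry
    and mixes the decoded patches in pixel space.  Probabilities are
    clipped to [0, 1] before weighting; the decoded image is clipped to
    [0, 1] and then peak-normalized (max pixel -> 1) or mass-normalized.
    """
    logits = np.asarray(token_logits, dtype=np.float64)
    g2, n = logits.shape
    g = int(round(math.sqrt(g2)))
    if g * g != g2:
        raise ValueError("token logits must cover a full square grid")
    if n != codec.config.n_codes:
        raise ValueError("logit width does not match the codec codebook")
    probs = np.clip(_softmax_np(logits), 0.0, 1.0)
    vectors = codec.codebook_vectors
    if mode == "latent":
        latents = probs @ vectors               # (g2, d) convex combination
        image = codec.decode_latents(latents, g)
    elif mode == "pixel":
        p = codec.config.patch_edge
        decoded = codec._decode_patches_np(vectors)      # (n, p*p)
        patches = probs @ decoded
        image = np.clip(codec.unpatchify(patches, g), 0.0, 1.0)
    else:
        raise ValueError("mode must be 'latent' or 'pixel'")
    peak = image.max()
    if peak <= 0:
        return ProbabilityMap(pixels=image, normalization="none")
    if normalization == "peak":
        image = image / peak
    elif normalization == "mass":
        image = image / image.sum()
    else:
        raise ValueError("normalization must be 'peak' or 'mass'")
    return ProbabilityMap(pixels=np.clip(image, 0.0, 1.0),
                          normalization=normalization)


@dataclasses.dataclass
class ModelBundle:
    """Everything needed for end-to-end prediction."""

    model: Transformer
    ref_codec: VQCodec
    prot_codec: VQCodec
    provider: object

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.save(outdir / "transformer.npz")
        self.ref_codec.save(outdir / "ref_codec.npz")
        self.prot_codec.save(outdir / "prot_codec.npz")

    @classmethod
    def load(cls, outdir: str | Path, provider) -> "ModelBundle":
        outdir = Path(outdir)
        return cls(model=Transformer.load(outdir / "transformer.npz"),
                   ref_codec=VQCodec.load(outdir / "ref_codec.npz"),
                   prot_codec=VQCodec.load(outdir / "prot_codec.npz"),
                   provider=provider)


def predict(sequence: str, reference_image: np.ndarray, bundle: ModelBundle,
            seed: int = 0, quartile: float = 0.25, k: int | None = None,
            map_mode: str = "latent", out: str | Path | None = None) -> dict:
    """Single-call pipeline: sequence + reference image -> localization map.

    Returns a dict with the probability map, the sampled threshold image
    (decode of the sampled grid re-binarized), the sampled token grid and
    the raw per-position logits.  With ``out`` set, also writes a heatmap
    PNG, a 32-bit float TIFF of the raw map, the threshold PNG and the
    token grid CSV.
    """
    cfg = bundle.model.config
    try:
        seq_emb = embed(sequence, bundle.provider, L_max=cfg.L_max)
    except (ValueError, KeyError) as exc:
        raise type(exc)(f"[sequence_embed] {exc}") from exc
    try:
        ref_grid = bundle.ref_codec.encode(reference_image)
    except ValueError as exc:
        raise ValueError(f"[image_codec] {exc}") from exc
    rng = np.random.default_rng(seed)
    grid, logits = generate_tokens(bundle.model, seq_emb, ref_grid, rng,
                                   quartile=quartile, k=k)
    pmap = build_probability_map(logits, bundle.prot_codec, mode=map_mode)
    decoded = bundle.prot_codec.decode(grid)
    threshold_image = binarize(decoded)
    result = {"probability_map": pmap, "threshold_image": threshold_image,
              "token_grid": grid, "token_logits": logits}
    if out is not None:
        _write_outputs(Path(out), result, reference_image)
    return result


def _write_outputs(outdir: Path, result: dict, reference: np.ndarray) -> None:
    import tifffile
    from PIL import Image

    outdir.mkdir(parents=True, exist_ok=True)
    pmap = result["probability_map"].pixels
    tifffile.imwrite(outdir / "probability_map.tif", pmap.astype(np.float32))
    Image.fromarray((result["threshold_image"] * 255).astype(np.uint8),
                    mode="L").save(outdir / "threshold_image.png")
    np.savetxt(outdir / "token_grid.csv", result["token_grid"].indices,
               fmt="%d", delimiter=",")
    _heatmap_png(outdir / "heatmap.png", pmap, reference)


def _heatmap_png(path: Path, pmap: np.ndarray, reference: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(reference, cmap="gray", interpolation="nearest")
    im = ax.imshow(pmap, cmap="inferno", alpha=0.6, interpolation="nearest",
                   vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, fraction=0.046, label="relative confidence")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
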