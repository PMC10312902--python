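"""End-to-end pipeline: dataset -> codecs -> transformer -> evaluation.

Bundles the three training phases and the standard evaluation /
attribution experiments behind a few functions so the command line, the
test suite and reproduction scripts all run the identical procedure.

Presets
-------
``mini``   64x64 images, 8x8-pixel patches (8x8 token grid), 64-entry
           codebooks, a 3-layer width-96 transformer and offline
           96-dimensional context-window embeddings; sized to train on a
           single CPU in minutes.
``full_scale``  256x256 images, 16x16 grids, 512-entry codebooks and a
           1000-residue context for externally supplied protein-language-
           model embeddings.  Config-complete; not exercised by the tests.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats

from .core_transformer import (ModelConfig, TokenStream, Transformer,
                               provider_checksum, train_transformer)
from .generation import ModelBundle, predict
from .image_codec import CodecConfig, VQCodec, binarize, train_codec
from .evaluation import in_mask_fraction, score_sample, summarize_scores
from .sequence_embed import ContextWindowProvider, LookupTableProvider, embed
from .synthetic_cells import (GeneratorConfig, LocalizationClass, SampleRecord,
                              NUCLEAR_MOTIF)

__all__ = ["PipelinePreset", "MINI", "FULL_SCALE", "train_pipeline",
           "prepare_streams", "evaluate_bundle", "nls_separation",
           "motif_recovery_rate", "overfit_protein_ce"]


@dataclasses.dataclass
class PipelinePreset:
    name: str
    generator: GeneratorConfig
    codec: CodecConfig
    model: ModelConfig
    d_seq: int
    provider_kind: str = "context"  # "context" | "lookup"

    def with_seed(self, seed: int) -> "PipelinePreset":
        return dataclasses.replace(
            self,
            codec=dataclasses.replace(self.codec, seed=seed),
            model=dataclasses.replace(self.model, seed=seed))

    def make_provider(self, seed: int):
        if self.provider_kind == "context":
            return ContextWindowProvider(seed=seed, d_seq=self.d_seq)
        return LookupTableProvider(seed=seed, d_seq=self.d_seq)


MINI = PipelinePreset(
    name="mini",
    generator=GeneratorConfig(image_size=64, patch_edge=8),
    codec=CodecConfig(patch_edge=8, n_codes=64, latent_dim=32, epochs=50),
    model=ModelConfig(L_max=64, grid_edge=8, n_ref=64, n_prot=64,
                      width=96, n_layers=3, n_heads=4, steps=2400),
    d_seq=96,
)

FULL_SCALE = PipelinePreset(
    name="full_scale",
    generator=GeneratorConfig(image_size=256, patch_edge=16,
                              seq_length=(50, 800)),
    codec=CodecConfig(patch_edge=16, n_codes=512, latent_dim=64, epochs=60),
    model=ModelConfig(L_max=1000, grid_edge=16, n_ref=512, n_prot=512,
                     width=512, n_layers=8, n_heads=8),
    d_seq=512,
)

PRESETS = {"mini": MINI, "full_scale": FULL_SCALE}


DIHEDRAL = [
    lambda a: a,
    lambda a: np.rot90(a, 1), lambda a: np.rot90(a, 2), lambda a: np.rot90(a, 3),
    lambda a: np.fliplr(a),
    lambda a: np.rot90(np.fliplr(a), 1), lambda a: np.rot90(np.fliplr(a), 2),
    lambda a: np.rot90(np.fliplr(a), 3),
]


def prepare_streams(records: list[SampleRecord], model: Transformer,
                    ref_codec: VQCodec, prot_codec: VQCodec,
                    provider, augment: bool = False) -> list[TokenStream]:
    """Tokenize and embed records into teacher-forcing streams.

    With ``augment`` each record yields all 8 dihedral orientations of its
    image pair (sequence unchanged), a train-time regularizer against
    memorizing individual nuclei.  Augmented streams skip the materialized
    input array.
    """
    transforms = DIHEDRAL if augment else DIHEDRAL[:1]
    streams = []
    for r in records:
        seq_emb = embed(r.sequence, provider, L_max=model.config.L_max)
        thresh = binarize(r.protein_image)
        for tf in transforms:
            ref_grid = ref_codec.encode(np.ascontiguousarray(
                tf(r.reference_image)))
            prot_grid = prot_codec.encode(np.ascontiguousarray(tf(thresh)))
            streams.append(model.assemble_stream(seq_emb, ref_grid, prot_grid,
                                                 materialize=not augment))
    return streams


def train_pipeline(train_records: list[SampleRecord],
                   preset: PipelinePreset = MINI, seed: int = 0,
                   steps: int | None = None,
                   log_dir: str | Path | None = None) -> ModelBundle:
    """Run all three phases on in-memory records and return the bundle."""
    preset = preset.with_seed(seed)
    log_dir = Path(log_dir) if log_dir is not None else None
    if log_dir is not None:
        log_dir.mkdir(parents=True, exist_ok=True)

    refs = [r.reference_image for r in train_records]
    prots = [r.protein_image for r in train_records]
    ref_codec, _ = train_codec(
        refs, "reference", preset.codec,
        log_path=log_dir / "ref_codec_loss.csv" if log_dir else None)
    prot_codec, _ = train_codec(
        prots, "threshold", preset.codec,
        log_path=log_dir / "prot_codec_loss.csv" if log_dir else None)

    provider = preset.make_provider(seed)
    model_cfg = preset.model
    if steps is not None:
        model_cfg = dataclasses.replace(model_cfg, steps=steps)
    model = Transformer(model_cfg)
    # hold out whole records for early stopping (augmented variants share
    # a sequence, so the split must be by record, not by stream)
    n_hold = max(2, int(round(model_cfg.early_stop_frac * len(train_records))))
    hold_rng = np.random.default_rng(seed + 23)
    hold_ids = set(hold_rng.choice(len(train_records), size=n_hold,
                                   replace=False).tolist())
    fit_records = [r for i, r in enumerate(train_records) if i not in hold_ids]
    hold_records = [r for i, r in enumerate(train_records) if i in hold_ids]
    streams = prepare_streams(fit_records, model, ref_codec, prot_codec,
                              provider, augment=True)
    holdout = prepare_streams(hold_records, model, ref_codec, prot_codec,
                              provider)
    frozen = {"ref_codec": ref_codec.checksum(),
              "prot_codec": prot_codec.checksum(),
              "provider": provider_checksum(provider)}
    model, _ = train_transformer(
        streams, model_cfg, frozen_checksums=frozen,
        recheck={"ref_codec": ref_codec.checksum,
                 "prot_codec": prot_codec.checksum,
                 "provider": lambda: provider_checksum(provider)},
        log_path=log_dir / "transformer_loss.csv" if log_dir else None,
        model=model, holdout_streams=holdout)
    return ModelBundle(model=model, ref_codec=ref_codec,
                       prot_codec=prot_codec, provider=provider)


def predict_records(bundle: ModelBundle, records: list[SampleRecord],
                    seed: int = 0) -> list[dict]:
    out = []
    for i, r in enumerate(records):
        res = predict(r.sequence, r.reference_image, bundle, seed=seed + i)
        res["record"] = r
        out.append(res)
    return out


def evaluate_bundle(bundle: ModelBundle, records: list[SampleRecord],
                    seed: int = 0, split: str = "val"):
    """Per-sample localization scores + summary for a record list."""
    predictions = predict_records(bundle, records, seed=seed)
    scores = [score_sample(p["record"].id, p["probability_map"].pixels,
                           p["record"].protein_image, p["record"].nucleus_mask,
                           p["record"].loc_class is LocalizationClass.NUCLEAR)
              for p in predictions]
    return summarize_scores(scores, split=split), predictions


def nls_separation(bundle: ModelBundle, records: list[SampleRecord],
                   seed: int = 0,
                   predictions: list[dict] | None = None) -> dict:
    """One-sided Mann-Whitney U: in-nucleus map mass of NLS-bearing vs
    NLS-free sequences.  NLS-bearing = sequences containing the planted
    nuclear motif."""
    predictions = predictions or predict_records(bundle, records, seed=seed)
    rho_nls, rho_free = [], []
    for p in predictions:
        rho = in_mask_fraction(p["probability_map"].pixels,
                               p["record"].nucleus_mask)
        (rho_nls if NUCLEAR_MOTIF in p["record"].sequence else rho_free).append(rho)
    u, pval = stats.mannwhitneyu(rho_nls, rho_free, alternative="greater")
    return {"mean_rho_nls": float(np.mean(rho_nls)),
            "mean_rho_free": float(np.mean(rho_free)),
            "n_nls": len(rho_nls), "n_free": len(rho_free),
            "U": float(u), "p_value": float(pval)}


def motif_recovery_rate(bundle: ModelBundle, records: list[SampleRecord],
                        seed: int = 0) -> dict:
    """Fraction of NUCLEAR sequences whose top attribution segment
    overlaps the planted nuclear motif occurrence."""
    from .attribution import attribute

    nuclear = [r for r in records
               if r.loc_class is LocalizationClass.NUCLEAR]
    hits, per_sample = 0, []
    for i, r in enumerate(nuclear):
        res = attribute(r.sequence, r.reference_image, bundle, seed=seed + i)
        report = res["report"]
        m_start = r.sequence.index(NUCLEAR_MOTIF)
        m_end = m_start + len(NUCLEAR_MOTIF) - 1
        hit = False
        if len(report):
            top = report.iloc[0]
            hit = not (top["end"] < m_start or top["start"] > m_end)
        hits += hit
        per_sample.append(hit)
    return {"n": len(nuclear), "hits": hits,
            "rate": hits / len(nuclear) if nuclear else float("nan"),
            "per_sample": per_sample}


def overfit_protein_ce(records: list[SampleRecord],
                       preset: PipelinePreset = MINI, seed: int = 0,
                       n_samples: int = 16, steps: int = 300) -> float:
    """Train on a tiny fixed subset and report final protein-token CE.

    A memorization check: with frozen codecs and embeddings, the token
    prior should drive teacher-forced protein-token cross-entropy to near
    zero on 16 samples within a few hundred steps.
    """
    subset = records[:n_samples]
    preset = preset.with_seed(seed)
    refs = [r.reference_image for r in subset]
    prots = [r.protein_image for r in subset]
    ref_codec, _ = train_codec(refs, "reference",
                               dataclasses.replace(preset.codec, epochs=20))
    prot_codec, _ = train_codec(prots, "threshold",
                                dataclasses.replace(preset.codec, epochs=20))
    provider = preset.make_provider(seed)
    # memorization check: no regularization, no early stopping
    cfg = dataclasses.replace(preset.model, steps=steps, batch_size=8,
                              lr=4e-3, warmup=20, dropout=0.0,
                              prot_input_dropout=0.0, early_stop_frac=0.0)
    model = Transformer(cfg)
    streams = prepare_streams(subset, model, ref_codec, prot_codec, provider)
    model, _ = train_transformer(streams, cfg, model=model)
    # reassemble with the trained embeddings, then score teacher-forced CE
    streams = prepare_streams(subset, model, ref_codec, prot_codec, provider)
    ces = []
    for s in streams:
        total, per_pos = model.joint_log_likelihood(s)
        ces.append(-per_pos[model.config.g2:].mean())
    return float(np.mean(ces))
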