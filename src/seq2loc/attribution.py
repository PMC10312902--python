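"""Attention-based attribution of localization to sequence features.

After generating a protein image, its patches are split into a
protein-"present" and a protein-"absent" group by mean patch intensity.
Each residue is then scored by the difference of mean attention it
receives from present-patch query positions versus absent-patch query
positions, averaged uniformly over layers and heads.  Residues the model
consults specifically when painting protein-positive patches score high;
on the synthetic benchmark the planted nuclear-localization motif should
surface as the top-ranked contiguous segment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_transformer import StreamLayout

__all__ = ["PatchPartition", "ResidueAttribution", "partition_patches",
           "attention_difference", "motif_report", "attribute"]


@dataclasses.dataclass
class PatchPartition:
    """Disjoint present/absent split of the g^2 protein-grid positions."""

    present_ids: np.ndarray
    absent_ids: np.ndarray
    cutoff: float

    def __post_init__(self):
        present = set(self.present_ids.tolist())
        absent = set(self.absent_ids.tolist())
        if present & absent:
            raise ValueError("present and absent sets overlap")


@dataclasses.dataclass
class ResidueAttribution:
    """Per-residue attention-difference scores over the true sequence."""

    scores: np.ndarray            # (L,) padding excluded
    highlighted: np.ndarray       # positions with score above the display cut
    display_threshold: float


def partition_patches(generated_image: np.ndarray, patch_edge: int,
                      cutoff: float | str = "mean") -> PatchPartition:
    """Split grid positions by mean patch intensity against a cutoff.

    ``cutoff='mean'`` uses the global image mean; a float is used as an
    absolute cutoff.  A patch is "present" iff its mean intensity >= cutoff.
    """
    image = np.asarray(generated_image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if image.shape[0] % patch_edge != 0:
        raise ValueError("image edge not divisible by patch edge")
    g = image.shape[0] // patch_edge
    patch_means = (image.reshape(g, patch_edge, g, patch_edge)
                   .transpose(0, 2, 1, 3).reshape(g * g, -1).mean(axis=1))
    cut = float(image.mean()) if cutoff == "mean" else float(cutoff)
    present = np.flatnonzero(patch_means >= cut)
    absent = np.flatnonzero(patch_means < cut)
    return PatchPartition(present_ids=present, absent_ids=absent, cutoff=cut)


def attention_difference(attention: np.ndarray, partition: PatchPartition,
                         layout: StreamLayout, seq_length: int,
                         ) -> ResidueAttribution:
    """Residue scores: mean attention from present-patch queries minus the
    mean from absent-patch queries.

    ``attention`` is the (layers, heads, T, T) stack of row-stochastic
    matrices captured during the generation pass; queries are restricted
    to the stream positions whose logits produced each protein token, keys
    to the residue positions of the true (unpadded) sequence.
    """
    attention = np.asarray(attention, dtype=np.float64)
    if attention.ndim != 4 or attention.shape[2] != layout.T:
        raise ValueError("attention record does not match the stream layout")
    if len(partition.present_ids) == 0 or len(partition.absent_ids) == 0:
        raise ValueError("present/absent partition is one-sided; choose a "
                         "different cutoff")
    key_pos = np.array([layout.seq_pos(r) for r in range(seq_length)])

    def group_mean(ids: np.ndarray) -> np.ndarray:
        q = np.array([layout.prot_query_pos(j) for j in ids])
        # mean over layers, heads and group queries -> per-residue vector
        return attention[:, :, q, :][:, :, :, key_pos].mean(axis=(0, 1, 2))

    scores = group_mean(partition.present_ids) - group_mean(partition.absent_ids)
    cut = scores.mean() + scores.std(ddof=0)
    highlighted = np.flatnonzero(scores > cut)
    return ResidueAttribution(scores=scores, highlighted=highlighted,
                              display_threshold=float(cut))


def motif_report(attribution: ResidueAttribution, sequence: str,
                 window: int = 5) -> pd.DataFrame:
    """Rank contiguous segments where the two patch groups disagree most.

    The magnitude of the attention difference is smoothed with a centered
    moving average; maximal runs above mean + 1 sd of the smoothed track
    are reported, ranked by peak.  Ranking on |score| keeps the report
    independent of the contrast's sign: which group consults a motif
    harder depends on which patches are the informative ones in a given
    dataset, but a residue the model treats very differently when painting
    protein-present versus protein-absent patches is a feature candidate
    either way.  Columns: start, end (inclusive), peak, segment.
    """
    scores = attribution.scores
    L = len(scores)
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    kernel = np.ones(window) / window
    smooth = np.convolve(np.abs(scores), kernel, mode="same")
    cut = smooth.mean() + smooth.std(ddof=0)
    above = smooth > cut
    segments = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            peak = float(smooth[start:i].max())
            segments.append({"start": start, "end": i - 1, "peak": peak,
                             "segment": sequence[start:i]})
            start = None
    segments.sort(key=lambda s: -s["peak"])
    return pd.DataFrame(segments, columns=["start", "end", "peak", "segment"])


def attribute(sequence: str, reference_image: np.ndarray, bundle,
              seed: int = 0, window: int = 5) -> dict:
    """End-to-end attribution: generate, partition, score, report.

    Generates the protein image for the sequence, captures attention in a
    teacher-forced pass over the completed stream, and returns the
    partition, the per-residue attribution and the ranked segment report.
    """
    from .generation import predict
    from .sequence_embed import embed

    cfg = bundle.model.config
    result = predict(sequence, reference_image, bundle, seed=seed)
    seq_emb = embed(sequence, bundle.provider, L_max=cfg.L_max)
    ref_grid = bundle.ref_codec.encode(reference_image)
    stream = bundle.model.assemble_stream(seq_emb, ref_grid,
                                          result["token_grid"])
    _, _, attention = bundle.model.forward(stream, capture_attention=True)
    generated = bundle.prot_codec.decode(result["token_grid"])
    partition = partition_patches(generated, bundle.prot_codec.config.patch_edge)
    attr = attention_difference(attention, partition, cfg.layout,
                                seq_length=len(sequence))
    report = motif_report(attr, sequence, window=window)
    return {"attribution": attr, "partition": partition, "report": report,
            "prediction": result}
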