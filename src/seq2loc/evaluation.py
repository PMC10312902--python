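"""Localization and reconstruction metrics.

The central quantity is the in-nucleus intensity fraction
rho = sum(image * mask) / sum(image): the share of an image's mass that
falls inside the nucleus mask.  From it derive

* nucleus proportion accuracy, npa = 1 - |rho(pred) - rho(truth)| — how
  closely the predicted map reproduces the ground-truth threshold image's
  nuclear mass share;
* a naive nuclear classifier, rho >= 0.5 (inclusive);
* the codec ceiling: classification accuracy when the ground-truth
  threshold image is merely round-tripped through the tokenizer, the best
  any generative model sampling that codebook can do.

Intersection-over-union of binarized maps is included as a generic
overlap score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .image_codec import VQCodec, binarize

__all__ = ["LocalizationScore", "in_mask_fraction", "nucleus_proportion_accuracy",
           "nuclear_classify", "iou", "codec_ceiling", "score_sample",
           "summarize_scores"]


def _check(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    if image.sum() <= 0:
        raise ValueError("image has zero total intensity; rho is undefined")
    return image, mask


def in_mask_fraction(image: np.ndarray, nucleus_mask: np.ndarray) -> float:
    """rho: fraction of total pixel intensity inside the nucleus mask."""
    image, mask = _check(image, nucleus_mask)
    return float((image * mask).sum() / image.sum())


def nucleus_proportion_accuracy(pred_map: np.ndarray, truth_threshold: np.ndarray,
                                nucleus_mask: np.ndarray) -> float:
    """npa = 1 - |rho(pred) - rho(truth)|; 1.0 means a perfect mass split."""
    rho_pred = in_mask_fraction(pred_map, nucleus_mask)
    rho_truth = in_mask_fraction(truth_threshold, nucleus_mask)
    return 1.0 - abs(rho_pred - rho_truth)


def nuclear_classify(map_or_image: np.ndarray, nucleus_mask: np.ndarray,
                     threshold: float = 0.5) -> bool:
    """Majority-mass nuclear call: True iff rho >= threshold (inclusive)."""
    return in_mask_fraction(map_or_image, nucleus_mask) >= threshold


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary images (binarized if needed)."""
    a = np.asarray(a) > 0.5
    b = np.asarray(b) > 0.5
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def mask_from_reference(reference_image: np.ndarray) -> np.ndarray:
    """Fallback nucleus mask from the reference channel: mean-threshold
    binarization followed by hole filling (for data without ground-truth
    masks)."""
    from scipy import ndimage

    rough = binarize(reference_image).astype(bool)
    return ndimage.binary_fill_holes(rough).astype(np.uint8)


@dataclasses.dataclass
class LocalizationScore:
    sample_id: str
    rho: float
    npa: float
    iou: float
    nuclear_call: bool
    true_nuclear: bool


def score_sample(sample_id: str, pred_map: np.ndarray, truth_image: np.ndarray,
                 nucleus_mask: np.ndarray, true_nuclear: bool) -> LocalizationScore:
    truth_thresh = binarize(truth_image)
    return LocalizationScore(
        sample_id=sample_id,
        rho=in_mask_fraction(pred_map, nucleus_mask),
        npa=nucleus_proportion_accuracy(pred_map, truth_thresh, nucleus_mask),
        iou=iou(binarize(pred_map), truth_thresh),
        nuclear_call=nuclear_classify(pred_map, nucleus_mask),
        true_nuclear=true_nuclear)


def summarize_scores(scores: list[LocalizationScore],
                     split: str = "val") -> pd.DataFrame:
    """Per-sample rows plus a summary row (n, mean, sd of each metric)."""
    df = pd.DataFrame([dataclasses.asdict(s) for s in scores])
    df["split"] = split
    df["correct"] = df["nuclear_call"] == df["true_nuclear"]
    summary = pd.DataFrame([{
        "sample_id": "__summary__", "split": split, "n": len(df),
        "rho": df["rho"].mean(), "npa": df["npa"].mean(),
        "iou": df["iou"].mean(),
        "accuracy_mean": df["correct"].mean(),
        "accuracy_sd": df["correct"].astype(float).std(ddof=0),
    }])
    return pd.concat([df, summary], ignore_index=True)


def codec_ceiling(samples: list, threshold_codec: VQCodec) -> dict:
    """Nuclear-classification accuracy on codec round-trips of ground truth.

    For each sample the ground-truth protein image is binarized, passed
    through encode/decode, and classified; the label is the classification
    of the untouched threshold image.  The result bounds what a generative
    model selecting tokens from this codebook can achieve.
    """
    if not threshold_codec.trained:
        raise ValueError("threshold codec is untrained")
    correct = []
    for s in samples:
        truth = binarize(s.protein_image)
        label = nuclear_classify(truth, s.nucleus_mask)
        recon = threshold_codec.decode(threshold_codec.encode(truth))
        call = nuclear_classify(recon, s.nucleus_mask)
        correct.append(call == label)
    correct = np.asarray(correct, dtype=float)
    return {"n": len(correct), "mean": float(correct.mean()),
            "sd": float(correct.std(ddof=0))}
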