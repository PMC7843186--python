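"""Segmentation and image-quality metrics.

Dice overlap for the standard glioma regions (whole tumor, tumor core,
enhancing tumor), pixelwise accuracy, rank-statistic ROC AUC, and the
MSE / PSNR pair used to score denoising.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "mse",
    "psnr",
    "dice",
    "pixel_accuracy",
    "roc_auc",
    "evaluate",
]

#: Sentinel returned by :func:`psnr` when the two images are identical.
PSNR_INF = float("inf")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean squared difference between two equal-shape images."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    _check_same_shape(ref, test)
    return float(np.mean((ref - test) ** 2))


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(peak^2 / MSE)``.

    Identical images have zero error; the conventional +inf sentinel is
    returned in that case.
    """
    err = mse(ref, test)
    if err == 0.0:
        return PSNR_INF
    return float(10.0 * np.log10(peak**2 / err))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` of two boolean masks.

    Two empty masks are a perfect (vacuous) match and score 1.0, the
    convention used when a tumor sub-region is absent from a slice.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    _check_same_shape(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def pixel_accuracy(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Fraction of pixels whose predicted class matches the truth."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    _check_same_shape(pred, true)
    return float(np.mean(pred == true))


def roc_auc(scores: np.ndarray, binary_truth: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Ties in ``scores`` receive averaged ranks, so constant scores give
    exactly 0.5. Raises if the truth vector is single-class (the AUC is
    undefined there).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(binary_truth).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: truth contains a single class")
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    probmap: np.ndarray | None = None,
    denoised: np.ndarray | None = None,
    clean: np.ndarray | None = None,
    tumor_classes: tuple[int, ...] = (2, 3, 4),
) -> dict:
    """Full metric record for one segmented image.

    Dice is reported for the three nested glioma regions (WT = edema ∪
    enhancing core ∪ necrosis, TC = enhancing core ∪ necrosis, ET =
    enhancing core). When a per-pixel probability map is given, the AUC
    of tumor-vs-rest probability is added (``nan`` when the truth is
    single-class); when a denoised/clean image pair is given, their MSE
    and PSNR are added.
    """
    from .phantom import region_masks

    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    _check_same_shape(pred, true)
    rm_pred = region_masks(pred)
    rm_true = region_masks(true)
    out = {
        "dice_WT": dice(rm_pred.wt, rm_true.wt),
        "dice_TC": dice(rm_pred.tc, rm_true.tc),
        "dice_ET": dice(rm_pred.et, rm_true.et),
        "accuracy": pixel_accuracy(pred, true),
    }
    if probmap is not None:
        probmap = np.asarray(probmap, dtype=float)
        # tumor score = total probability mass on the tumor classes
        tumor_score = probmap[..., tumor_classes].sum(axis=-1)
        truth = np.isin(true, tumor_classes)
        if truth.any() and not truth.all():
            out["auc"] = roc_auc(tumor_score.ravel(), truth.ravel())
        else:
            out["auc"] = float("nan")
    if denoised is not None and clean is not None:
        out["mse"] = mse(clean, denoised)
        out["psnr"] = psnr(clean, denoised)
    return out
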