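"""Evaluation stack: MSE/PSNR for denoising, threshold-sweep ROC with AUC,
accuracy curve with its maximum (MAA), and field-of-view mask construction.

The ROC sweep varies a rounding threshold T over an even grid in [0, 1]
(default 256 values); a pixel is predicted "vessel" when response >= T.
TPR = TP/(TP+FN) and FPR = FP/(FP+TN) are computed inside the field of
view when a mask is given (pixels outside the FOV are excluded entirely —
counting them as background would inflate the true-negative count).  AUC
is the trapezoidal area under TPR(FPR) with the endpoints (0,0) and (1,1)
appended, so a constant response scores 0.5.  Accuracy at T is
(TP+TN)/total; its maximum over the sweep is the maximum accuracy (MAA),
reported with its threshold and operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from ._validation import GrayImage, as_image, same_shape
from .medialness import MultiscaleResult

__all__ = ["EvalReport", "mse", "psnr", "fov_mask", "roc_analysis"]


@dataclass(frozen=True)
class EvalReport:
    """Threshold-sweep evaluation summary.

    ``thresholds``, ``tpr``, ``fpr`` and ``accuracy`` are aligned arrays
    (tpr/fpr nonincreasing in the threshold); ``auc`` the area under the
    ROC curve; ``maa`` the maximum accuracy with its threshold and the
    TPR/FPR at that operating point.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    accuracy: np.ndarray
    auc: float
    maa: float
    maa_threshold: float
    tpr_at_maa: float
    fpr_at_maa: float


def mse(reference: GrayImage, test: GrayImage) -> float:
    """Mean squared difference between two equally sized images."""
    a = as_image(reference, "reference")
    b = as_image(test, "test")
    same_shape(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(reference: GrayImage, test: GrayImage, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE) in dB.

    Higher means closer to the reference; identical images return +inf.
    """
    err = mse(reference, test)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def fov_mask(gray: GrayImage, threshold: float) -> np.ndarray:
    """Binary field-of-view mask by simple thresholding.

    Pixels with intensity >= threshold are kept; only the largest
    connected component survives and its holes are filled, which isolates
    the circular camera aperture of a fundus photograph from stray bright
    pixels.
    """
    img = as_image(gray)
    mask = img >= threshold
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def roc_analysis(
    response: Union[MultiscaleResult, np.ndarray],
    truth: np.ndarray,
    fov: Optional[np.ndarray] = None,
    n_thresholds: int = 256,
) -> EvalReport:
    """Threshold-sweep ROC/accuracy analysis of a [0, 1] response map
    against a binary ground truth, optionally restricted to a FOV mask.

    Ties (response exactly equal to the threshold) count as vessel.
    """
    resp = response.response if isinstance(response, MultiscaleResult) else np.asarray(response, dtype=float)
    truth = np.asarray(truth)
    same_shape(resp, truth, "response and truth")
    uniq = np.unique(truth)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("truth mask must be binary (0/1)")
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        same_shape(resp, fov, "response and fov")
        sel = fov
    else:
        sel = np.ones_like(resp, dtype=bool)

    r = resp[sel].ravel()
    t = truth[sel].ravel().astype(bool)
    pos = np.sort(r[t])
    neg = np.sort(r[~t])
    n_pos, n_neg = pos.size, neg.size
    total = max(n_pos + n_neg, 1)

    thresholds = np.linspace(0.0, 1.0, int(n_thresholds))
    tp = n_pos - np.searchsorted(pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    tpr = tp / n_pos if n_pos else np.zeros_like(thresholds)
    fpr = fp / n_neg if n_neg else np.zeros_like(thresholds)
    accuracy = (tp + (n_neg - fp)) / total

    # ROC curve in ascending-FPR order with explicit endpoints
    xs = np.concatenate([[0.0], fpr[::-1], [1.0]])
    ys = np.concatenate([[0.0], tpr[::-1], [1.0]])
    auc = float(np.trapezoid(ys, xs))

    i = int(np.argmax(accuracy))
    return EvalReport(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        accuracy=accuracy,
        auc=auc,
        maa=float(accuracy[i]),
        maa_threshold=float(thresholds[i]),
        tpr_at_maa=float(tpr[i]),
        fpr_at_maa=float(fpr[i]),
    )
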