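"""Quantitative evaluation metrics.

Detection of HRA columns is scored with set arithmetic (TPR, PPV and
Dice coefficient, all in percent); tomogram fidelity with PSNR and mean
local SSIM on Z-scored images, using the reference image's value range
as the peak / data range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["DetectionScore", "detection_score", "psnr", "ssim"]


@dataclass
class DetectionScore:
    """Column-detection confusion counts and derived percentages.

    Undefined rates (empty truth or empty detection) are reported as
    NaN sentinels rather than raising.
    """

    tp: int
    fp: int
    fn: int
    tpr: float
    ppv: float
    dsc: float


def detection_score(detected, truth, width: int) -> DetectionScore:
    """Score a detected column set against ground-truth HRA columns."""
    detected = set(int(c) for c in detected)
    truth = set(int(c) for c in truth)
    for name, cols in (("detected", detected), ("truth", truth)):
        if any(c < 0 or c >= width for c in cols):
            raise ValueError(f"{name} columns fall outside [0, {width})")
    tp = len(detected & truth)
    fp = len(detected - truth)
    fn = len(truth - detected)
    tpr = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    dsc = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return DetectionScore(tp=tp, fp=fp, fn=fn, tpr=tpr, ppv=ppv, dsc=dsc)


def psnr(test: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak = range of the reference.

    Identical images return ``inf``.  Intended for Z-scored tomograms,
    whose peak is otherwise undefined.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((test - ref) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(ref.max() - ref.min())
    return 10.0 * np.log10(peak**2 / mse)


def ssim(test: np.ndarray, ref: np.ndarray) -> float:
    """Mean local SSIM (11-pixel Gaussian window, sigma 1.5), data range
    taken from the reference image."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("shape mismatch")
    return float(
        structural_similarity(
            test,
            ref,
            data_range=float(ref.max() - ref.min()),
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )
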