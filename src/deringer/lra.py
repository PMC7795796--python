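"""Low-level ring artifact (LRA) correction by homogeneous-area
intensity equalization.

Miscalibrated detector pixels leave small constant column offsets that
are invisible in the sinogram but reconstruct into faint rings.  The
correcting idea: column-wise neighbouring homogeneous areas of the
extracted texture should, without artifacts, share the same mean.  Each
iteration

1. extracts the RTV texture of the working sinogram,
2. suppresses noise with a 1-D column-wise adaptive Wiener filter
   (used only for the analysis, never added back),
3. detects homogeneous areas column-wise,
4. sweeps left-to-right computing per-column additive correction
   factors that equalise neighbouring homogeneous-area means,
5. detrends the correction vector with a Savitzky-Golay filter whose
   frame halves every iteration (so only the spiky artifact component
   is corrected while the texture's structural trend is preserved), and
6. rebuilds the sinogram as ``S_s + T + C_d``.

Iterations repeat on the corrected sinogram until the shared texture
convergence rule fires or ``max_iters`` is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .rtv import RTVParams, extract_texture, texture_converged

__all__ = [
    "LRAParams",
    "LRAResult",
    "denoise_texture",
    "homogeneous_mask",
    "correction_factors",
    "detrend",
    "effective_sg_frame",
    "apply_correction",
    "remove_lra",
]

logger = logging.getLogger(__name__)


@dataclass
class LRAParams:
    """Equalization-loop parameters.

    r1:
        Convergence threshold of the shared texture stopping rule.
    l_wiener:
        Window length (odd, >= 3) of the column-wise adaptive Wiener
        noise filter.
    sg_order:
        Polynomial order of the Savitzky-Golay detrending filter.
    sg_frame:
        Initial (first-iteration) Savitzky-Golay frame length; halves
        each iteration, floored to the next odd value.  The frame must
        be short enough that the trend tracks the structural drift the
        correction sweep accumulates across columns; a frame much wider
        than that drift's correlation length re-injects it as rings.
    max_iters:
        Safety cap on correction iterations.
    """

    r1: float = 0.01
    l_wiener: int = 5
    sg_order: int = 3
    sg_frame: int = 31
    max_iters: int = 10

    def __post_init__(self) -> None:
        if self.l_wiener < 3 or self.l_wiener % 2 == 0:
            raise ValueError("l_wiener must be odd and >= 3")
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_order + 1:
            raise ValueError("sg_frame must be odd and > sg_order + 1")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class LRAResult:
    """Outcome of the LRA correction loop."""

    n_iterations: int
    converged: bool
    history: list[dict] = field(default_factory=list)


def denoise_texture(texture: np.ndarray, l_wiener: int) -> np.ndarray:
    """Column-wise 1-D adaptive (local mean/variance) Wiener filter.

    The classical pixel-wise minimum-mean-square filter: the noise power
    is estimated as the average local variance, and each pixel is pulled
    towards its local mean in proportion to how much of its local
    variance is explained by noise.  Local statistics use replicate
    padding so detector-edge rows are not biased towards zero.
    """
    texture = np.asarray(texture, dtype=float)
    if l_wiener > texture.shape[0]:
        raise ValueError("l_wiener exceeds the number of rows")
    local_mean = uniform_filter1d(texture, l_wiener, axis=0, mode="nearest")
    local_sq = uniform_filter1d(texture**2, l_wiener, axis=0, mode="nearest")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    noise = local_var.mean()
    gain = np.where(
        local_var > noise, (local_var - noise) / np.maximum(local_var, 1e-300), 0.0
    )
    return local_mean + gain * (texture - local_mean)


def homogeneous_mask(denoised: np.ndarray) -> np.ndarray:
    """Column-wise homogeneity mask: ``|T_f(x, y)| <= mean_x |T_f(., y)|``.

    Magnitudes are compared (a signed reading would label strongly
    negative pixels homogeneous); the equality case is included.
    """
    denoised = np.asarray(denoised, dtype=float)
    mag = np.abs(denoised)
    return mag <= mag.mean(axis=0, keepdims=True)


def correction_factors(denoised: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-column additive correction factors from a left-to-right sweep.

    The column with the smaller index is always the reference; the
    working texture is updated in place during the sweep so corrections
    accumulate, anchored at ``C[0] = 0``.  A column sharing no
    homogeneous rows with its left neighbour inherits that neighbour's
    factor.
    """
    work = np.array(denoised, dtype=float, copy=True)
    mask = np.asarray(mask, dtype=bool)
    if work.shape != mask.shape:
        raise ValueError("texture and mask shapes differ")
    n_cols = work.shape[1]
    factors = np.zeros(n_cols)
    for y in range(1, n_cols):
        shared = mask[:, y] & mask[:, y - 1]
        if shared.any():
            factors[y] = work[shared, y - 1].mean() - work[shared, y].mean()
        else:
            factors[y] = factors[y - 1]
        work[:, y] += factors[y]
    return factors


def effective_sg_frame(sg_frame: int, sg_order: int, iteration: int, n_cols: int) -> int:
    """Savitzky-Golay frame for a given iteration (1-based).

    The initial frame halves each iteration (``f / 2**(i-1)``), floored
    to the next odd value, clamped below at the smallest admissible odd
    frame (> order + 1, and at least 5) and above at the signal length.
    """
    frame = sg_frame // 2 ** (iteration - 1)
    if frame % 2 == 0:
        frame += 1
    floor = max(sg_order + 2, 5)
    if floor % 2 == 0:
        floor += 1
    if frame < floor:
        logger.debug("SG frame clamped from %d to %d", frame, floor)
        frame = floor
    cap = n_cols if n_cols % 2 else n_cols - 1
    return min(frame, cap)


def detrend(
    factors: np.ndarray, sg_order: int, sg_frame: int, iteration: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split correction factors into spiky residual and smooth trend.

    The trend is the Savitzky-Golay smoothing of the factors with
    polynomial edge fitting, so any degree <= ``sg_order`` polynomial is
    reproduced exactly (and detrends to zero); the residual
    ``C_d = C - t`` carries the per-column artifact offsets.
    """
    factors = np.asarray(factors, dtype=float)
    frame = effective_sg_frame(sg_frame, sg_order, iteration, factors.size)
    trend = savgol_filter(factors, frame, sg_order, mode="interp")
    return factors - trend, trend


def apply_correction(
    smoothed: np.ndarray, texture: np.ndarray, residual: np.ndarray
) -> np.ndarray:
    """Rebuild the corrected sinogram ``S_s + T + C_d``.

    The detrended factors are broadcast across rows and applied to the
    *raw* texture (the Wiener-denoised copy is analysis-only).
    """
    return smoothed + texture + np.asarray(residual, dtype=float)[np.newaxis, :]


def remove_lra(
    sino: np.ndarray,
    params: LRAParams | None = None,
    rtv_params: RTVParams | None = None,
) -> tuple[np.ndarray, LRAResult]:
    """Run the iterative LRA equalization loop on a sinogram."""
    params = params or LRAParams()
    rtv_params = rtv_params or RTVParams()
    current = np.array(sino, dtype=float, copy=True)
    if not np.all(np.isfinite(current)):
        raise ValueError("sinogram contains non-finite values")
    t_first = t_prev = None
    history: list[dict] = []
    converged = False
    iterations_run = 0
    for iteration in range(1, params.max_iters + 1):
        decomp = extract_texture(current, rtv_params)
        texture = decomp.texture
        if t_first is None:
            t_first = texture
        elif texture_converged(texture, t_prev, t_first, params.r1):
            converged = True
            break
        t_prev = texture

        denoised = denoise_texture(texture, params.l_wiener)
        mask = homogeneous_mask(denoised)
        factors = correction_factors(denoised, mask)
        residual, _trend = detrend(
            factors, params.sg_order, params.sg_frame, iteration
        )
        current = apply_correction(decomp.smoothed, texture, residual)
        iterations_run = iteration
        history.append(
            {
                "iteration": iteration,
                "sg_frame": effective_sg_frame(
                    params.sg_frame, params.sg_order, iteration, factors.size
                ),
                "max_abs_residual": float(np.abs(residual).max()),
            }
        )
        logger.info(
            "LRA iteration %d: max |C_d| = %.4g",
            iteration,
            history[-1]["max_abs_residual"],
        )
    logger.info(
        "LRA loop finished after %d correction passes (converged=%s)",
        iterations_run,
        converged,
    )
    return current, LRAResult(
        n_iterations=iterations_run, converged=converged, history=history
    )
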