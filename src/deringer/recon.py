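"""Tomographic reconstruction and intensity standardization.

Reconstruction uses filtered back projection with a cosine frequency
filter by default (half-scan geometry, angles uniform over [0, 180)),
followed by min-max normalization to [0, 1].  Quality metrics are
computed on Z-scored tomograms so that global intensity shifts
introduced by a correction cannot masquerade as structural error.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import iradon

from .phantoms import projection_angles

__all__ = ["fbp_reconstruct", "zscore"]


def fbp_reconstruct(sino: np.ndarray, filter_name: str = "cosine") -> np.ndarray:
    """Filtered back projection of an (angles x detector) sinogram.

    Returns a ``det_width`` square tomogram min-max normalized to
    [0, 1]; a constant reconstruction (e.g. from an all-zero sinogram)
    degenerates to all zeros.
    """
    sino = np.asarray(sino, dtype=float)
    if sino.ndim != 2:
        raise ValueError("expected a 2-D sinogram")
    theta = projection_angles(sino.shape[0])
    tomo = iradon(
        sino.T,
        theta=theta,
        filter_name=filter_name,
        circle=True,
        output_size=sino.shape[1],
    )
    lo, hi = tomo.min(), tomo.max()
    if hi == lo:
        return np.zeros_like(tomo)
    return (tomo - lo) / (hi - lo)


def zscore(img: np.ndarray) -> np.ndarray:
    """Standardize an image to zero mean and unit standard deviation."""
    img = np.asarray(img, dtype=float)
    sd = img.std()
    if sd == 0:
        raise ValueError("constant image has no Z-score standardization")
    return (img - img.mean()) / sd
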