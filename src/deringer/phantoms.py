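"""Synthetic phantoms and sinogram formation.

Three phantoms spanning the usual complexity ladder of ring-artifact
studies: a homogeneous ball (single-material sample), the modified
Shepp-Logan head phantom (multi-material sample) and a Siemens star
(fine radial detail, highly complex sample).  Phantoms are generated in
the tomogram domain and forward projected with the Radon transform.

Sinogram axis convention used throughout the package: axis 0 indexes the
projection angle (M rows), axis 1 the detector column (N pixels).  A
defective detector element therefore appears as a vertical stripe.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import radon

PHANTOM_KINDS = ("ball", "shepp_logan", "siemens_star")

# Modified (contrast-enhanced) Shepp-Logan ellipse table:
# (additive value, semi-axis a, semi-axis b, x0, y0, rotation [deg]).
_SHEPP_LOGAN_ELLIPSES = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric pixel-centre grid on [-1, 1] x [-1, 1] (y axis up)."""
    c = (size - 1) / 2.0
    coords = (np.arange(size) - c) / c
    x, y = np.meshgrid(coords, -coords)
    return x, y


def make_phantom(kind: str, size: int, *, spokes: int = 32) -> np.ndarray:
    """Generate a square test phantom in the tomogram domain.

    Parameters
    ----------
    kind:
        One of ``"ball"``, ``"shepp_logan"``, ``"siemens_star"``.
    size:
        Side length in pixels (>= 16).
    spokes:
        Spoke count of the Siemens star; must be even so that the star
        is point symmetric.  Ignored for the other kinds.
    """
    if size < 16:
        raise ValueError(f"phantom size must be >= 16, got {size}")
    if kind == "ball":
        x, y = _grid(size)
        return (x * x + y * y <= 0.75**2).astype(float)
    if kind == "shepp_logan":
        x, y = _grid(size)
        img = np.zeros((size, size))
        for value, a, b, x0, y0, phi_deg in _SHEPP_LOGAN_ELLIPSES:
            phi = np.deg2rad(phi_deg)
            xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
            yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
            img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += value
        return img
    if kind == "siemens_star":
        if spokes % 2:
            raise ValueError("spoke count must be even")
        x, y = _grid(size)
        theta = np.arctan2(y, x)
        inside = x * x + y * y <= 0.9**2
        return (inside & (np.cos(spokes / 2.0 * 2.0 * theta) > 0)).astype(float)
    raise ValueError(f"unknown phantom kind {kind!r}; valid kinds: {PHANTOM_KINDS}")


def forward_project(
    img: np.ndarray, n_angles: int = 800, det_width: int = 1648
) -> np.ndarray:
    """Radon transform of ``img`` onto an ``n_angles x det_width`` sinogram.

    Angles are sampled uniformly over [0, 180) degrees (half scan).  The
    image is embedded centred in a ``det_width`` square canvas, so
    ``det_width`` must cover the image diagonal.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    diag = int(np.ceil(np.hypot(*img.shape)))
    if det_width < diag:
        raise ValueError(
            f"det_width {det_width} does not cover the image diagonal {diag}"
        )
    canvas = np.zeros((det_width, det_width))
    # align the image centre with the rotation centre (shape // 2)
    r0 = det_width // 2 - img.shape[0] // 2
    c0 = det_width // 2 - img.shape[1] // 2
    canvas[r0 : r0 + img.shape[0], c0 : c0 + img.shape[1]] = img
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sino = radon(canvas, theta=theta, circle=True)
    return np.ascontiguousarray(sino.T)


def projection_angles(n_angles: int) -> np.ndarray:
    """Uniform half-scan angle grid in degrees, matching forward_project."""
    return np.linspace(0.0, 180.0, n_angles, endpoint=False)


def add_noise(sino: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Add i.i.d. Gaussian noise of absolute standard deviation ``sigma``.

    The study convention interprets ``sigma`` on the sinogram's
    normalized [0, 1] intensity scale, i.e. noise is added *before* the
    sinogram is stretched to the detector dynamic range.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    sino = np.asarray(sino, dtype=float)
    if sigma == 0:
        return sino.copy()
    rng = np.random.default_rng(seed)
    return sino + rng.normal(0.0, sigma, size=sino.shape)
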