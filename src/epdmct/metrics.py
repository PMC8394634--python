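"""Image-quality evaluation: absolute difference, L2 evaluation, SSIM, profiles.

The L2 evaluation ``E(z) = ||e - z||_2`` is deliberately *unnormalized* (no
1/J): its magnitude therefore depends on the pixel count, and values quoted
for 128x128 reconstructions are on the scale sqrt(J) times the per-pixel
RMS error.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["pixel_abs_diff", "l2_error", "ssim", "line_profile"]


def _pair(e: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(e, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if e.shape != z.shape:
        raise ValueError("images must have the same number of pixels")
    return e, z


def pixel_abs_diff(e: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise absolute difference ``|e_j - z_j|`` (subtraction image)."""
    e, z = _pair(e, z)
    return np.abs(e - z)


def l2_error(e: np.ndarray, z: np.ndarray) -> float:
    """Unnormalized Euclidean evaluation ``E(z) = ||e - z||_2``."""
    e, z = _pair(e, z)
    return float(np.linalg.norm(e - z))


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float = 1.0,
    *,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Single-scale structural similarity with the reference defaults.

    Gaussian weighting window (sigma 1.5, truncated at radius 5, i.e. the
    classic 11x11 tap filter), population statistics, stabilizers
    ``C1 = (k1 L)**2`` and ``C2 = (k2 L)**2`` with ``L = data_range``. The
    SSIM map is cropped by the filter radius before averaging, matching the
    standard implementation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be 2-D arrays of identical shape")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)
    if min(a.shape) < 2 * radius + 1:
        raise ValueError("images are smaller than the 11x11 SSIM window")
    fa = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(a, **fa)
    uy = gaussian_filter(b, **fa)
    vx = gaussian_filter(a * a, **fa) - ux * ux
    vy = gaussian_filter(b * b, **fa) - uy * uy
    vxy = gaussian_filter(a * b, **fa) - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    core = s[radius:-radius, radius:-radius]
    return float(core.mean(dtype=np.float64))


def line_profile(img: np.ndarray, row: int) -> np.ndarray:
    """Pixel values of one image row, in column order."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("img must be a 2-D array")
    if not 0 <= row < img.shape[0]:
        raise IndexError(f"row {row} out of range for image with {img.shape[0]} rows")
    return img[row].copy()
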