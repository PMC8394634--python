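"""Shepp-Logan phantom generation and sinogram simulation.

The phantom is the high-contrast ("modified") variant of the Shepp-Logan
head phantom: ten overlapping ellipses whose additive densities sum to
values in [0, 1], rasterized on a square grid by testing pixel centers.
Sinograms are simulated by forward projection through the exact line-length
system matrix, optionally with additive white Gaussian noise at a stated
SNR in dB.

Two SNR conventions are supported (papers rarely state which they use):

``"peak"`` (default)
    sigma = max(y) / 10**(snr_db / 20) — noise power relative to the peak
    signal amplitude, PSNR-style.
``"power"``
    sigma**2 = mean(y**2) / 10**(snr_db / 10) — noise power relative to the
    mean signal power, so the realized 10*log10(sum(y**2)/sum(delta**2))
    equals ``snr_db`` up to sampling error.

Negative noisy measurements are clipped to zero: the divergence family and
the multiplicative update require nonnegative data (``y**gamma`` with
fractional ``gamma`` is undefined for negative values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ProjectionGeometry, SystemMatrix, forward_project

__all__ = [
    "Ellipse",
    "PhantomImage",
    "Sinogram",
    "modified_shepp_logan_ellipses",
    "rasterize",
    "shepp_logan_phantom",
    "simulate_sinogram",
    "add_noise",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse in normalized [-1, 1] image coordinates."""

    center_x: float
    center_y: float
    semi_axis_a: float  # along the ellipse's own x axis
    semi_axis_b: float  # along the ellipse's own y axis
    rotation: float  # degrees, counterclockwise
    additive_density: float

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class PhantomImage:
    """A nonnegative image on a square grid, stored as a flat vector."""

    values: np.ndarray
    image_size: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.image_size**2:
            raise ValueError("values length must equal image_size**2")
        object.__setattr__(self, "values", v)

    @property
    def image(self) -> np.ndarray:
        """The (image_size, image_size) 2-D view, row 0 at the top."""
        return self.values.reshape(self.image_size, self.image_size)


@dataclass(frozen=True)
class Sinogram:
    """A flat vector of ray sums with its geometry and noise provenance."""

    values: np.ndarray
    geometry: ProjectionGeometry
    noise_meta: dict = field(default_factory=lambda: {"kind": "noise-free"})

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.geometry.n_rays:
            raise ValueError("sinogram length must equal n_views * n_bins")
        object.__setattr__(self, "values", v)

    @property
    def array(self) -> np.ndarray:
        """The (n_views, n_bins) 2-D view (view-major ray order)."""
        return self.values.reshape(self.geometry.n_views, self.geometry.n_bins)


# Standard high-contrast ("modified") Shepp-Logan parameter table:
# density, semi-axis a, semi-axis b, x0, y0, rotation (deg).
_MODIFIED_SHEPP_LOGAN = (
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
)


def modified_shepp_logan_ellipses() -> list[Ellipse]:
    """The ten-ellipse high-contrast Shepp-Logan parameter table."""
    return [
        Ellipse(
            center_x=x0,
            center_y=y0,
            semi_axis_a=a,
            semi_axis_b=b,
            rotation=phi,
            additive_density=d,
        )
        for d, a, b, x0, y0, phi in _MODIFIED_SHEPP_LOGAN
    ]


def rasterize(ellipses: list[Ellipse], image_size: int) -> PhantomImage:
    """Rasterize additive ellipses by pixel-center membership.

    A pixel's value is the sum of ``additive_density`` over all ellipses
    containing its center (no anti-aliasing); negative sums are clipped to 0.
    Normalized coordinates: the grid spans [-1, 1] on both axes with row 0 at
    the top (y increases upward).
    """
    if image_size < 1:
        raise ValueError("image_size must be >= 1")
    n = image_size
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    X, Y = np.meshgrid(c, -c)
    img = np.zeros((n, n))
    for e in ellipses:
        t = np.deg2rad(e.rotation)
        dx, dy = X - e.center_x, Y - e.center_y
        xr = dx * np.cos(t) + dy * np.sin(t)
        yr = -dx * np.sin(t) + dy * np.cos(t)
        inside = (xr / e.semi_axis_a) ** 2 + (yr / e.semi_axis_b) ** 2 <= 1.0
        img[inside] += e.additive_density
    return PhantomImage(values=np.clip(img, 0.0, None).ravel(), image_size=n)


def shepp_logan_phantom(image_size: int = 128) -> PhantomImage:
    """The modified Shepp-Logan phantom rasterized at ``image_size``."""
    return rasterize(modified_shepp_logan_ellipses(), image_size)


def simulate_sinogram(A: SystemMatrix, phantom: PhantomImage) -> Sinogram:
    """Noise-free sinogram ``y = A e`` of a phantom."""
    y = forward_project(A, phantom.values)
    return Sinogram(values=y, geometry=A.geometry)


def add_noise(
    s: Sinogram,
    snr_db: float,
    seed: int,
    convention: str = "peak",
) -> Sinogram:
    """Add white Gaussian noise at a stated SNR, clipping negatives to 0.

    Parameters
    ----------
    s : Sinogram
        Noise-free sinogram.
    snr_db : float
        Signal-to-noise ratio in decibels; ``inf`` returns ``s`` unchanged.
    seed : int
        Seed for the dedicated noise RNG stream; same seed, same output.
    convention : {"peak", "power"}
        How the noise standard deviation is derived from ``snr_db`` (see
        module docstring).
    """
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return s
        raise ValueError("snr_db must be finite or +inf")
    y = s.values
    if convention == "peak":
        sigma = float(y.max()) / 10.0 ** (snr_db / 20.0)
    elif convention == "power":
        sigma = float(np.sqrt(np.mean(y**2) / 10.0 ** (snr_db / 10.0)))
    else:
        raise ValueError(f"unknown SNR convention {convention!r}")
    rng = np.random.default_rng(seed)
    noisy = np.clip(y + rng.normal(0.0, sigma, size=y.shape), 0.0, None)
    meta = {
        "kind": "gaussian",
        "snr_db": float(snr_db),
        "seed": int(seed),
        "convention": convention,
        "sigma": sigma,
    }
    return replace(s, values=noisy, noise_meta=meta)
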