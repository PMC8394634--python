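"""Parallel-beam acquisition geometry and the sparse system matrix.

The projection operator ``A`` maps a pixelized image (flattened row-major,
length ``J = image_size**2``) to a stack of line integrals (length
``I = n_views * n_bins``). Entry ``A[i, j]`` is the intersection length of
ray ``i`` with pixel ``j``, computed exactly by parametric traversal of the
pixel grid (Siddon-style), one ray per detector bin through the bin center.

Coordinate conventions (fixed, documented, relied on by tests):

* The image is an ``n x n`` grid of unit pixels centered on the rotation
  isocenter. Array row 0 is the *top* of the image; the y axis points up,
  so pixel ``(r, c)`` covers ``x in [-n/2 + c, -n/2 + c + 1]`` and
  ``y in [n/2 - r - 1, n/2 - r]``.
* A view at angle ``theta`` (degrees) has detector axis
  ``u = (cos(theta), sin(theta))`` and ray direction
  ``v = (-sin(theta), cos(theta))``; bin ``b`` is the line
  ``t -> off_b * u + t * v`` with ``off_b = (b - (n_bins - 1)/2) * spacing``.
* Rays are indexed view-major: ``i = view * n_bins + bin``.
* Angles sample ``[0, angular_range)`` half-open, equally spaced.

Rays that miss the image square have all-zero rows. They are retained in the
matrix but flagged in :attr:`SystemMatrix.valid_rays` so that divergence and
update sums can skip them (their contribution is identically zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "ProjectionGeometry",
    "SystemMatrix",
    "build_system_matrix",
    "forward_project",
    "back_project",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam sampling scheme.

    Parameters
    ----------
    n_views : int
        Number of projection angles, equally spaced over ``angular_range``.
    n_bins : int
        Detector bins per view.
    image_size : int
        Pixels per side of the square reconstruction grid.
    angular_range : float
        Angular span in degrees (default 180; views sample the half-open
        interval ``[0, angular_range)``).
    detector_spacing : float or None
        Bin width in pixel units. ``None`` (default) chooses
        ``image_size * sqrt(2) / n_bins`` so the detector array exactly
        covers the image diagonal footprint.
    pixel_size : float
        Physical pixel width; the grid is dimensionless by default.
    """

    n_views: int
    n_bins: int
    image_size: int
    angular_range: float = 180.0
    detector_spacing: float | None = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_views", "n_bins", "image_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.angular_range <= 0:
            raise ValueError("angular_range must be positive")
        if self.detector_spacing is not None and self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_rays(self) -> int:
        """Total ray count ``I = n_views * n_bins``."""
        return self.n_views * self.n_bins

    @property
    def n_pixels(self) -> int:
        """Image-domain dimension ``J = image_size**2``."""
        return self.image_size**2

    @property
    def spacing(self) -> float:
        """Resolved detector spacing (diagonal coverage when unset)."""
        if self.detector_spacing is not None:
            return float(self.detector_spacing)
        return self.image_size * np.sqrt(2.0) / self.n_bins

    @property
    def angles_deg(self) -> np.ndarray:
        """View angles in degrees, ``[0, angular_range)`` half-open."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    def bin_offsets(self) -> np.ndarray:
        """Signed detector-bin center offsets from the isocenter."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.spacing

    def to_dict(self) -> dict:
        return {
            "n_views": self.n_views,
            "n_bins": self.n_bins,
            "image_size": self.image_size,
            "angular_range": self.angular_range,
            "detector_spacing": self.detector_spacing,
            "pixel_size": self.pixel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return cls(**d)


@dataclass
class SystemMatrix:
    """Sparse nonnegative projection operator with its validity mask.

    Attributes
    ----------
    matrix : scipy.sparse.csr_matrix
        The ``I x J`` intersection-length matrix.
    geometry : ProjectionGeometry
    valid_rays : ndarray of bool, shape (I,)
        True for rays whose row has at least one positive entry; rays that
        miss the image square are False and must be excluded from divergence
        and update sums.
    """

    matrix: sparse.csr_matrix
    geometry: ProjectionGeometry
    valid_rays: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def T(self) -> sparse.csc_matrix:
        return self.matrix.T

    def row_sums(self) -> np.ndarray:
        """Per-ray total chord length through the image square."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def column_sums(self) -> np.ndarray:
        """Per-pixel total ray weight (sensitivity image for MLEM)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()


def _view_weights(
    theta_deg: float, n: int, n_bins: int, spacing: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersection lengths of one view's rays with the pixel grid.

    Vectorized over bins: collects the ray parameters at every crossing of a
    vertical or horizontal grid line, sorts them, and attributes each segment
    between consecutive crossings to the pixel containing its midpoint.
    Returns ``(bin_index, flat_pixel_index, length)`` triples.
    """
    th = np.deg2rad(theta_deg)
    ux, uy = np.cos(th), np.sin(th)
    vx, vy = -np.sin(th), np.cos(th)
    offs = (np.arange(n_bins) - (n_bins - 1) / 2.0) * spacing
    half = n / 2.0
    lines = -half + np.arange(n + 1)

    eps = 1e-12
    parts = []
    if abs(vx) > eps:
        parts.append((lines[None, :] - offs[:, None] * ux) / vx)
    if abs(vy) > eps:
        parts.append((lines[None, :] - offs[:, None] * uy) / vy)
    ts = np.concatenate(parts, axis=1)
    ts.sort(axis=1)

    t0, t1 = ts[:, :-1], ts[:, 1:]
    seg = t1 - t0
    mid = 0.5 * (t0 + t1)
    mx = offs[:, None] * ux + mid * vx
    my = offs[:, None] * uy + mid * vy
    col = np.floor(mx + half).astype(np.int64)
    row = np.floor(half - my).astype(np.int64)
    ok = (seg > eps) & (col >= 0) & (col < n) & (row >= 0) & (row < n)
    b_idx = np.broadcast_to(np.arange(n_bins)[:, None], seg.shape)
    return b_idx[ok], row[ok] * n + col[ok], seg[ok]


def build_system_matrix(geometry: ProjectionGeometry) -> SystemMatrix:
    """Build the sparse ray/pixel intersection-length matrix.

    Deterministic for a fixed geometry. Every entry is a nonnegative exact
    chord length (scaled by ``pixel_size``); duplicate (ray, pixel) segments
    produced by a ray re-entering a pixel cannot occur for straight lines,
    but the COO construction sums them safely regardless.
    """
    n = geometry.image_size
    rows, cols, vals = [], [], []
    for view, theta in enumerate(geometry.angles_deg):
        b, pj, w = _view_weights(theta, n, geometry.n_bins, geometry.spacing)
        rows.append(view * geometry.n_bins + b)
        cols.append(pj)
        vals.append(w)
    matrix = sparse.csr_matrix(
        (
            np.concatenate(vals) * geometry.pixel_size,
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(geometry.n_rays, geometry.n_pixels),
    )
    matrix.sum_duplicates()
    valid = np.diff(matrix.indptr) > 0
    return SystemMatrix(matrix=matrix, geometry=geometry, valid_rays=valid)


def _as_image_vector(x: np.ndarray, J: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x.ravel()
    if x.shape != (J,):
        raise ValueError(f"image vector has length {x.size}, expected {J}")
    return x


def forward_project(A: SystemMatrix, x: np.ndarray) -> np.ndarray:
    """Compute the sinogram ``A @ x`` of an image (2-D array or length-J vector)."""
    x = _as_image_vector(x, A.shape[1])
    return A.matrix @ x


def back_project(A: SystemMatrix, s: np.ndarray) -> np.ndarray:
    """Compute the image-domain adjoint ``A.T @ s`` of a sinogram vector."""
    s = np.asarray(s, dtype=float).ravel()
    if s.shape != (A.shape[0],):
        raise ValueError(f"sinogram vector has length {s.size}, expected {A.shape[0]}")
    return A.matrix.T @ s
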