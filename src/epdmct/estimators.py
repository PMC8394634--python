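"""scikit-learn style reconstruction estimators.

A reconstructor consumes a sinogram and produces an image, so it is exposed
with the familiar ``fit`` idiom: hyperparameters in ``__init__`` (plain
attributes, ``get_params``/``set_params`` via :class:`~sklearn.base.BaseEstimator`),
the data in ``fit``, results in trailing-underscore attributes. The thin
functional layer these wrap lives in :mod:`epdmct.recon`.

Example
-------
>>> from epdmct import (ProjectionGeometry, build_system_matrix,
...                     shepp_logan_phantom, simulate_sinogram)
>>> from epdmct.estimators import PDEMReconstructor
>>> geom = ProjectionGeometry(n_views=24, n_bins=24, image_size=16)
>>> A = build_system_matrix(geom)
>>> sino = simulate_sinogram(A, shepp_logan_phantom(16))
>>> rec = PDEMReconstructor(gamma=1.3, alpha=1.2, n_iter=20).fit(
...     sino, system_matrix=A)
>>> rec.image_.shape
(16, 16)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .divergence import EPDMParams
from .geometry import ProjectionGeometry, SystemMatrix, build_system_matrix
from .phantom import Sinogram
from .recon import fbp as _fbp
from .recon import reconstruct

__all__ = ["PDEMReconstructor", "MLEMReconstructor", "FBPReconstructor"]


def _resolve_inputs(y, system_matrix, geometry):
    """Accept a Sinogram (carrying geometry) or array + explicit geometry."""
    if isinstance(y, Sinogram):
        values = y.values
        geometry = geometry or y.geometry
    else:
        values = np.asarray(y, dtype=float).ravel()
    if system_matrix is None:
        if geometry is None:
            raise ValueError(
                "provide a SystemMatrix, or a Sinogram/geometry to build one"
            )
        system_matrix = build_system_matrix(geometry)
    return values, system_matrix


class PDEMReconstructor(BaseEstimator):
    """Iterative reconstruction by extended power-divergence minimization.

    Parameters
    ----------
    gamma, alpha : float
        Divergence-family exponents (gamma > 0, alpha >= 0);
        (1, 1) reduces to MLEM.
    h : float
        Relaxation exponent of the multiplicative update (default 1).
    n_iter : int
        Number of iterations.
    z0 : float or None
        Constant initial pixel value; ``None`` uses the data-scale default
        mean(y)/mean(row sums).

    Attributes
    ----------
    image_ : ndarray, shape (image_size, image_size)
        The reconstruction after ``n_iter`` iterations.
    trace_ : ReconTrace
        Per-iteration objective values (and E/SSIM when a ground truth was
        supplied to ``fit``).
    """

    def __init__(
        self,
        gamma: float = 1.0,
        alpha: float = 1.0,
        h: float = 1.0,
        n_iter: int = 200,
        z0: float | None = None,
    ):
        self.gamma = gamma
        self.alpha = alpha
        self.h = h
        self.n_iter = n_iter
        self.z0 = z0

    def _params(self) -> EPDMParams:
        return EPDMParams(gamma=self.gamma, alpha=self.alpha, h=self.h)

    def fit(
        self,
        X,
        y=None,
        *,
        system_matrix: SystemMatrix | None = None,
        geometry: ProjectionGeometry | None = None,
        ground_truth: np.ndarray | None = None,
        snapshot_at: set[int] | None = None,
        track_ssim: bool = True,
    ):
        """Reconstruct from the sinogram ``X``.

        ``X`` may be a :class:`~epdmct.phantom.Sinogram` or a flat/2-D array
        (then ``system_matrix`` or ``geometry`` is required). ``y`` is
        ignored (sklearn API compatibility).
        """
        values, A = _resolve_inputs(X, system_matrix, geometry)
        trace = reconstruct(
            A,
            values,
            self._params(),
            n_iters=self.n_iter,
            z0_value=self.z0,
            ground_truth=ground_truth,
            snapshot_at=snapshot_at,
            track_ssim=track_ssim,
        )
        n = A.geometry.image_size
        self.system_matrix_ = A
        self.trace_ = trace
        self.image_ = trace.image.reshape(n, n)
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted reconstruction (sklearn-transform flavored)."""
        if not hasattr(self, "image_"):
            raise AttributeError("fit must be called before transform")
        return self.image_


class MLEMReconstructor(PDEMReconstructor):
    """Classical MLEM: the (gamma, alpha) = (1, 1) member with h = 1."""

    def __init__(self, n_iter: int = 200, z0: float | None = None):
        super().__init__(gamma=1.0, alpha=1.0, h=1.0, n_iter=n_iter, z0=z0)

    def get_params(self, deep: bool = True) -> dict:
        return {"n_iter": self.n_iter, "z0": self.z0}


class FBPReconstructor(BaseEstimator):
    """Filtered backprojection (Shepp-Logan windowed ramp) baseline."""

    def __init__(self):
        pass

    def fit(self, X, y=None, *, geometry: ProjectionGeometry | None = None):
        self.image_ = _fbp(X, geometry)
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "image_"):
            raise AttributeError("fit must be called before transform")
        return self.image_
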