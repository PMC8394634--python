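r"""The extended power-divergence family and the reconstruction objective.

For parameters :math:`\gamma > 0` and :math:`\alpha \ge 0` the divergence
between nonnegative ``p`` and positive ``q`` is

.. math::

    \Phi_{\gamma,\alpha}(p, q)
        = \sum_i \int_{p_i}^{q_i} \frac{s^\gamma - p_i^\gamma}{s^{\gamma\alpha}}\, ds .

The integrand has the sign of :math:`s - p_i`, so every term is nonnegative
and vanishes iff :math:`p_i = q_i`. Closed forms follow from the two-power
antiderivative, with two special branches where an exponent hits a pole:

* :math:`\gamma\alpha = 1`:
  :math:`(q^\gamma - p^\gamma)/\gamma - p^\gamma \log(q/p)`
  (the generalized Kullback-Leibler divergence when :math:`\gamma = 1`);
* :math:`\gamma\alpha = 1 + \gamma`:
  :math:`\log(q/p) + ((p/q)^\gamma - 1)/\gamma`
  (the Itakura-Saito-form / reverse-KL member when :math:`\gamma = 1`);
* otherwise, with :math:`a = 1 + \gamma - \gamma\alpha` and
  :math:`b = 1 - \gamma\alpha`:
  :math:`(q^a - p^a)/a - p^\gamma (q^b - p^b)/b`.

Setting :math:`(\gamma, \alpha) = (1, 0)` gives half the squared L2
distance; :math:`\alpha = 1` recovers the classical one-parameter
power-divergence family (KL at :math:`\gamma = 1`, Neyman :math:`\chi^2` at
:math:`\gamma = 2`, generalized Hellinger otherwise).

Terms with :math:`p_i = 0` converge iff :math:`\gamma(1 - \alpha) > -1`
(equivalently :math:`a > 0`), where they equal :math:`q^a / a`; otherwise
the term — and the sum — is :math:`+\infty`, reported as ``inf`` rather
than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .geometry import SystemMatrix, forward_project

__all__ = ["EPDMParams", "epdm", "epdm_quadrature", "objective"]

#: Branch-selection tolerance: |gamma*alpha - pole| below this routes to the
#: special closed form, avoiding catastrophic cancellation in the 1/a, 1/b
#: factors of the general antiderivative.
BRANCH_TOL = 1e-12


@dataclass(frozen=True)
class EPDMParams:
    """The (gamma, alpha, h) triple governing divergence and update.

    gamma > 0 and alpha >= 0 select the family member; h is the relaxation
    (step-size) exponent of the multiplicative update, default 1 (h = 0
    degenerates to the identity map and is allowed for completeness).
    """

    gamma: float
    alpha: float
    h: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.alpha >= 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.h >= 0:
            raise ValueError(f"h must be >= 0, got {self.h}")

    @property
    def is_mlem(self) -> bool:
        return self.gamma == 1.0 and self.alpha == 1.0


def _validate_pq(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p < 0):
        raise ValueError("p must be nonnegative")
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive")
    return p, q


def epdm_terms(p: np.ndarray, q: np.ndarray, params: EPDMParams) -> np.ndarray:
    """Per-element divergence terms (closed form). See module docstring."""
    p, q = _validate_pq(p, q)
    g, ga = params.gamma, params.gamma * params.alpha
    out = np.empty_like(q)
    pos = p > 0
    pp, qp = p[pos], q[pos]
    with np.errstate(divide="ignore"):
        if abs(ga - 1.0) < BRANCH_TOL:
            out[pos] = (qp**g - pp**g) / g - pp**g * np.log(qp / pp)
            out[~pos] = q[~pos] ** g / g
        elif abs(ga - (1.0 + g)) < BRANCH_TOL:
            out[pos] = np.log(qp / pp) + ((pp / qp) ** g - 1.0) / g
            out[~pos] = np.inf
        else:
            a, b = 1.0 + g - ga, 1.0 - ga
            out[pos] = (qp**a - pp**a) / a - pp**g * (qp**b - pp**b) / b
            out[~pos] = q[~pos] ** a / a if a > 0 else np.inf
    # exact-equality terms are identically zero; also clamps the tiny
    # negative round-off the subtraction forms can leave near p == q
    out[p == q] = 0.0
    return np.maximum(out, 0.0)


def epdm(p: np.ndarray, q: np.ndarray, params: EPDMParams) -> float:
    """Closed-form divergence, summed in ascending element order."""
    return float(np.sum(epdm_terms(p, q, params)))


def epdm_quadrature(
    p: np.ndarray, q: np.ndarray, params: EPDMParams, *, rtol: float = 1e-10
) -> float:
    """Adaptive numerical integration of the defining integrand.

    Verification oracle for :func:`epdm`; orders of magnitude slower and
    used only in tests.
    """
    p, q = _validate_pq(p, q)
    g, ga = params.gamma, params.gamma * params.alpha
    total = 0.0
    for pi, qi in zip(p, q):
        if pi == qi:
            continue
        if pi == 0.0 and 1.0 + g - ga <= 0:
            return float("inf")

        def integrand(s: float, pi: float = pi) -> float:
            return (s**g - pi**g) / s**ga

        val, _ = integrate.quad(integrand, pi, qi, epsrel=rtol, limit=200)
        total += val
    return total


def objective(
    A: SystemMatrix, y: np.ndarray, x: np.ndarray, params: EPDMParams
) -> float:
    """The tomographic objective ``V(x) = Phi_{gamma,alpha}(y, A x)``.

    Summed over valid rays only (rays missing the image square carry no
    information and would contribute 0/0 artifacts). Requires ``x > 0`` and
    a strictly positive forward projection on every valid ray.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape != (A.shape[0],):
        raise ValueError(f"y has length {y.size}, expected {A.shape[0]}")
    Ax = forward_project(A, x)
    m = A.valid_rays
    if np.any(Ax[m] <= 0):
        bad = int(np.flatnonzero(m & (Ax <= 0))[0])
        raise ValueError(
            f"degenerate support: forward projection vanishes on valid ray {bad}"
        )
    return epdm(y[m], Ax[m], params)
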