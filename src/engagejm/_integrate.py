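"""Quadrature helpers for hazard integrals of the form exp(quadratic).

The cumulative dropout hazard under the shared-parameter model requires
integrals of exp{c0 + c1*s + c2*s^2} over baseline-hazard pieces; for
c2 != 0 there is no elementary antiderivative, so these are evaluated
numerically.  Two entry points are provided:

* :func:`exp_quad_integral` — adaptive Gauss-Legendre with panel bisection
  to an absolute tolerance (used on scalar integrals, e.g. when simulating
  event times);
* :func:`gauss_legendre` — cached fixed-order nodes/weights on [-1, 1] for
  the vectorised likelihood evaluations, where a fixed rule of moderate
  order already resolves the smooth integrand to near machine precision.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["gauss_legendre", "exp_quad_integral"]


@lru_cache(maxsize=None)
def gauss_legendre(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights on [-1, 1]."""
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


def _panel(c0: float, c1: float, c2: float, a: float, b: float, order: int) -> float:
    x, w = gauss_legendre(order)
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    s = mid + half * x
    return half * float(np.dot(w, np.exp(c0 + s * (c1 + c2 * s))))


def exp_quad_integral(
    c0: float,
    c1: float,
    c2: float,
    a: float,
    b: float,
    tol: float = 1e-10,
    order: int = 20,
    _depth: int = 0,
) -> float:
    """Adaptive evaluation of ``integral_a^b exp(c0 + c1*s + c2*s^2) ds``.

    Bisects panels until the fixed-order estimate agrees with its two-half
    refinement to within ``tol`` (absolute), then keeps the refined value.
    """
    if b <= a:
        return 0.0
    coarse = _panel(c0, c1, c2, a, b, order)
    mid = 0.5 * (a + b)
    left = _panel(c0, c1, c2, a, mid, order)
    right = _panel(c0, c1, c2, mid, b, order)
    fine = left + right
    # absolute tolerance with a relative floor so steep exponential growth
    # (huge integrand values) cannot force unbounded recursion
    if abs(fine - coarse) <= max(tol, 1e-13 * abs(fine)) or _depth >= 30:
        return fine
    half_tol = 0.5 * tol
    return exp_quad_integral(c0, c1, c2, a, mid, half_tol, order, _depth + 1) + exp_quad_integral(
        c0, c1, c2, mid, b, half_tol, order, _depth + 1
    )
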