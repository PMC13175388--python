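"""B-spline bases, design matrices and roughness penalties.

The boundary function is represented as Q(t) = sum_k beta_k phi_k(t), where
{phi_k} is a clamped B-spline basis of order ``p`` (degree ``p - 1``) with
``K`` basis functions on a closed domain.  Every estimator in the package
builds its design matrix and penalty through this module.

Two roughness penalties are provided:

* ``second_derivative_integral`` — the curvature penalty
  ``int (Q''(t))^2 dt``, assembled exactly by Gauss–Legendre quadrature on
  each knot span (the integrand is piecewise polynomial, so a fixed rule is
  exact).
* ``second_order_difference`` — the P-spline surrogate penalising squared
  second differences of adjacent spline coefficients.

Both are symmetric positive semi-definite; their null spaces contain the
coefficient vectors of constant and linear functions (integral flavor) or of
constant and arithmetic-progression coefficient sequences (difference flavor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "PenaltyMatrix",
    "InvalidSpecError",
    "OutOfDomainError",
    "build_spline_spec",
    "evaluate_basis",
    "build_penalty",
    "greville_abscissae",
]

PENALTY_FLAVORS = ("second_derivative_integral", "second_order_difference")


class InvalidSpecError(ValueError):
    """Raised for degenerate domains, K < p, or unknown penalty flavors."""


class OutOfDomainError(ValueError):
    """Raised when evaluation is requested outside the spline domain."""


@dataclass(frozen=True)
class SplineSpec:
    """A clamped B-spline basis of order ``order_p`` with ``n_basis_K`` functions.

    The knot vector has length ``n_basis_K + order_p``: each boundary knot is
    repeated ``order_p`` times and the ``n_basis_K - order_p`` interior knots
    are equally spaced on the open domain.
    """

    domain_lo: float
    domain_hi: float
    n_basis_K: int
    order_p: int
    knots: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return self.order_p - 1

    def as_dict(self) -> dict:
        return {
            "domain_lo": self.domain_lo,
            "domain_hi": self.domain_hi,
            "n_basis_K": self.n_basis_K,
            "order_p": self.order_p,
            "knots": np.asarray(self.knots).tolist(),
        }


@dataclass(frozen=True)
class PenaltyMatrix:
    """Symmetric PSD penalty ``S`` so that beta' S beta measures roughness."""

    matrix_S: np.ndarray
    flavor: str

    @property
    def K(self) -> int:
        return self.matrix_S.shape[0]


def build_spline_spec(
    domain_lo: float, domain_hi: float, n_basis_K: int, order_p: int = 4
) -> SplineSpec:
    """Construct a clamped spline spec with equally spaced interior knots.

    ``order_p = 4`` gives cubic splines.  ``n_basis_K == order_p`` yields the
    Bernstein-like basis with no interior knots.
    """
    if not np.isfinite(domain_lo) or not np.isfinite(domain_hi) or domain_lo >= domain_hi:
        raise InvalidSpecError(
            f"degenerate domain [{domain_lo}, {domain_hi}]: need domain_lo < domain_hi"
        )
    order_p = int(order_p)
    n_basis_K = int(n_basis_K)
    if order_p < 2:
        raise InvalidSpecError(f"spline order must be >= 2, got {order_p}")
    if n_basis_K < order_p:
        raise InvalidSpecError(
            f"need at least as many basis functions as the order: K={n_basis_K} < p={order_p}"
        )
    n_interior = n_basis_K - order_p
    interior = np.linspace(domain_lo, domain_hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(order_p, float(domain_lo)), interior, np.full(order_p, float(domain_hi))]
    )
    return SplineSpec(
        domain_lo=float(domain_lo),
        domain_hi=float(domain_hi),
        n_basis_K=n_basis_K,
        order_p=order_p,
        knots=knots,
    )


def _check_in_domain(spec: SplineSpec, times: np.ndarray) -> None:
    tol = 1e-12 * max(1.0, abs(spec.domain_lo), abs(spec.domain_hi))
    if times.size and (times.min() < spec.domain_lo - tol or times.max() > spec.domain_hi + tol):
        raise OutOfDomainError(
            f"evaluation times in [{times.min()}, {times.max()}] fall outside the "
            f"spline domain [{spec.domain_lo}, {spec.domain_hi}]; no extrapolation"
        )


def evaluate_basis(spec: SplineSpec, times) -> np.ndarray:
    """Design matrix Phi with entries phi_k(t_i), shape (len(times), K).

    Rows form a partition of unity; at a clamped boundary only the terminal
    basis function is nonzero.  Times outside the domain raise
    :class:`OutOfDomainError` — extrapolation is never silent.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    _check_in_domain(spec, times)
    x = np.clip(times, spec.domain_lo, spec.domain_hi)
    return BSpline.design_matrix(x, spec.knots, spec.degree, extrapolate=False).toarray()


def basis_derivative_columns(spec: SplineSpec, times, nu: int = 2) -> np.ndarray:
    """Matrix of nu-th derivatives phi_k^(nu)(t_i), shape (len(times), K)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    _check_in_domain(spec, times)
    b = BSpline(spec.knots, np.eye(spec.n_basis_K), spec.degree, extrapolate=False)
    vals = b.derivative(nu)(np.clip(times, spec.domain_lo, spec.domain_hi))
    return np.nan_to_num(vals)


def greville_abscissae(spec: SplineSpec) -> np.ndarray:
    """Sites xi_k at which coefficients beta_k = a + b*xi_k represent a + b*t."""
    p = spec.order_p
    t = spec.knots
    return np.array([t[k + 1 : k + p].mean() for k in range(spec.n_basis_K)])


def build_penalty(spec: SplineSpec, flavor: str = "second_derivative_integral") -> PenaltyMatrix:
    """Assemble the roughness penalty matrix S for a spec.

    For the integral flavor, beta' S beta equals int (Q'')^2 exactly when
    Q = sum_k beta_k phi_k; the quadrature degree is chosen to integrate the
    piecewise-polynomial integrand without error.  For the difference flavor,
    S = D2' D2 with D2 the second-order difference operator on coefficients.
    """
    if flavor not in PENALTY_FLAVORS:
        raise InvalidSpecError(
            f"unknown penalty flavor {flavor!r}; choose one of {PENALTY_FLAVORS}"
        )
    K = spec.n_basis_K
    if flavor == "second_order_difference":
        if K < 3:
            raise InvalidSpecError("difference penalty needs at least 3 basis functions")
        D2 = np.diff(np.eye(K), n=2, axis=0)
        S = D2.T @ D2
    else:
        if spec.order_p < 3:
            raise InvalidSpecError(
                "integral curvature penalty needs order >= 3 (second derivatives)"
            )
        # (phi_j'' phi_k'') is a polynomial of degree 2*(p-3) on each span;
        # a Gauss-Legendre rule with p-2 nodes integrates degree 2p-5 exactly.
        n_nodes = max(1, spec.order_p - 2)
        xg, wg = leggauss(n_nodes)
        spans = np.unique(spec.knots)
        S = np.zeros((K, K))
        for lo, hi in zip(spans[:-1], spans[1:]):
            mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
            nodes = mid + half * xg
            d2 = basis_derivative_columns(spec, nodes, nu=2)  # (n_nodes, K)
            S += half * (d2.T * wg) @ d2
        S = 0.5 * (S + S.T)
    return PenaltyMatrix(matrix_S=S, flavor=flavor)
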