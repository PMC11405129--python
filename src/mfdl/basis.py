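"""Predetermined basis systems and quadrature on the unit interval.

Functional layers represent weight surfaces and bias functions as expansions
in a fixed (non-trainable) basis on [0, 1].  Two families are provided:
clamped uniform B-splines of arbitrary order (order 1 gives indicator
functions of equal subintervals) and the trivial constant basis.  Integrals
over [0, 1] are approximated by the composite trapezoid rule on a uniform
grid; trapezoid is exact for the piecewise-linear parts of low-order bases
and converges at O(h^2) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSystem",
    "QuadratureGrid",
    "make_bspline_system",
    "eval_basis",
    "uniform_grid",
    "quad_integrate",
]

DEFAULT_GRID_SIZE = 50
DEFAULT_BSPLINE_ORDER = 5
DEFAULT_N_BASIS = 7


class BasisConfigError(ValueError):
    """Raised for inconsistent basis configuration (e.g. n_basis < order)."""


@dataclass(frozen=True)
class BasisSystem:
    """A family of fixed basis functions eta_j on [0, 1].

    Parameters
    ----------
    kind
        ``"bspline"`` for clamped uniform B-splines.
    order
        Polynomial order (degree + 1).  ``order=5`` is the fifth-order
        B-spline family; ``order=1`` yields indicator functions.
    n_basis
        Number of basis functions J.
    knots
        Full clamped knot vector of length ``n_basis + order``.
    """

    kind: str
    order: int
    n_basis: int
    knots: np.ndarray = field(repr=False)

    def eval(self, points) -> np.ndarray:
        """Evaluate all basis functions at ``points``; shape (len(points), J)."""
        return eval_basis(self, points)

    def __eq__(self, other):  # array field breaks the generated __eq__
        return (
            isinstance(other, BasisSystem)
            and self.kind == other.kind
            and self.order == other.order
            and self.n_basis == other.n_basis
            and np.array_equal(self.knots, other.knots)
        )

    def __hash__(self):
        return hash((self.kind, self.order, self.n_basis))


def make_bspline_system(order: int = DEFAULT_BSPLINE_ORDER,
                        n_basis: int = DEFAULT_N_BASIS) -> BasisSystem:
    """Build a clamped uniform B-spline basis of given order on [0, 1].

    The knot vector repeats 0 and 1 ``order`` times each (clamping, so the
    basis is well defined at both endpoints) with ``n_basis - order``
    uniformly spaced interior knots.  The resulting family is a partition of
    unity: at every t the J values are nonnegative and sum to one.
    """
    if order < 1:
        raise BasisConfigError(f"order must be >= 1, got {order}")
    if n_basis < order:
        raise BasisConfigError(
            f"n_basis ({n_basis}) must be >= order ({order}) for a clamped B-spline basis"
        )
    degree = order - 1
    n_interior = n_basis - order
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(order), interior, np.ones(order)])
    return BasisSystem(kind="bspline", order=order, n_basis=n_basis, knots=knots)


def eval_basis(sys: BasisSystem, points) -> np.ndarray:
    """Evaluate eta_j at each point; entry (i, j) = eta_j(points[i])."""
    pts = np.atleast_1d(np.asarray(points, dtype=float))
    if pts.ndim != 1:
        raise ValueError("points must be one-dimensional")
    if pts.size and (pts.min() < 0.0 or pts.max() > 1.0):
        bad = pts[(pts < 0.0) | (pts > 1.0)]
        raise ValueError(f"points outside [0, 1]: {bad[:5]}")
    degree = sys.order - 1
    return BSpline.design_matrix(pts, sys.knots, degree, extrapolate=False).toarray()


@dataclass(frozen=True)
class QuadratureGrid:
    """Uniform grid on [0, 1] with composite-trapezoid weights summing to 1."""

    points: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    size: int = 0

    def __eq__(self, other):
        return isinstance(other, QuadratureGrid) and self.size == other.size

    def __hash__(self):
        return hash(("quadgrid", self.size))


def uniform_grid(size: int = DEFAULT_GRID_SIZE) -> QuadratureGrid:
    if size < 2:
        raise ValueError("grid needs at least 2 points")
    pts = np.linspace(0.0, 1.0, size)
    h = 1.0 / (size - 1)
    w = np.full(size, h)
    w[0] = w[-1] = h / 2.0
    return QuadratureGrid(points=pts, weights=w, size=size)


def quad_integrate(values, grid: QuadratureGrid) -> float | np.ndarray:
    """Trapezoid approximation of the integral of ``values`` over [0, 1].

    ``values`` may be a vector of length ``grid.size`` or an array whose last
    axis has that length (integration along the last axis).
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != grid.size:
        raise ValueError(
            f"values last axis ({v.shape[-1]}) does not match grid size ({grid.size})"
        )
    out = v @ grid.weights
    return float(out) if out.ndim == 0 else out
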