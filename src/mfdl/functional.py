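"""Omics variant functions and the functional layers of a single-modality subnet.

A sample's marker vector g_i at rescaled positions t_1 < ... < t_p is treated
as a Dirac comb G_i(t) = sum_j g_ij delta(t - t_j), so the integral of G_i
against any smooth function collapses exactly to the marker sum
sum_j g_ij f(t_j).  The first functional layer therefore needs no quadrature:
its design matrix Phi[i, l] = sum_j g_ij eta_l(t_j) is computed exactly.

Deeper layers act on smooth hidden functions Z(t) sampled on a quadrature
grid; their bivariate weight surfaces beta(t, s) and bias functions alpha0(t)
are tensor-product / plain expansions in fixed bases, and the integral over s
is approximated by the trapezoid rule.

Each layer class implements an explicit ``forward``/``backward`` pair; the
backward pass is the exact reverse-mode derivative of the discretized forward
computation, with basis evaluations treated as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSystem, QuadratureGrid, eval_basis

__all__ = [
    "OmicsVariantFunction",
    "HiddenFunction",
    "CovariateBlock",
    "FunctionalLayerParams",
    "build_variant_function",
    "dirac_design",
    "first_layer_forward",
    "hidden_layer_forward",
    "output_layer_forward",
    "ACTIVATIONS",
    "Param",
    "FunctionalFirstLayer",
    "FunctionalHiddenLayer",
    "FunctionalOutputLayer",
    "DenseLayer",
]


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _tanh(x):
    return np.tanh(x)


def _tanh_grad(x, y):
    return 1.0 - y * y


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x, y):
    return (x > 0.0).astype(float)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _sigmoid_grad(x, y):
    return y * (1.0 - y)


def _identity(x):
    return x


def _identity_grad(x, y):
    return np.ones_like(x)


#: name -> (f, df) where df takes (pre-activation, output) and returns f'(pre)
ACTIVATIONS = {
    "tanh": (_tanh, _tanh_grad),
    "relu": (_relu, _relu_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "identity": (_identity, _identity_grad),
}


def get_activation(name: str):
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

class DuplicatePositionError(ValueError):
    pass


@dataclass
class OmicsVariantFunction:
    """A modality's sample-by-marker matrix plus positions rescaled to [0, 1]."""

    values: np.ndarray
    positions01: np.ndarray
    modality_id: str = "omics"

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class HiddenFunction:
    """Per-sample hidden function values on a quadrature grid."""

    grid: QuadratureGrid
    values: np.ndarray  # (n_samples, grid.size)


@dataclass
class CovariateBlock:
    """Covariates X (n x q) with coefficient vector alpha (q,); q may be 0."""

    X: np.ndarray
    alpha: np.ndarray

    def linear_term(self) -> np.ndarray:
        if self.X.shape[1] == 0:
            return np.zeros(self.X.shape[0])
        return self.X @ self.alpha


@dataclass
class FunctionalLayerParams:
    """Basis-coefficient parameters of one functional layer.

    ``weight_coeffs`` holds w_{lj} (J_in x J_out) of the surface
    beta(t, s) = sum_l sum_j w_lj eta_l(s) eta_j(t); ``bias_coeffs`` holds the
    coefficients b_j of alpha0(t) = sum_j b_j eta_j(t).
    """

    weight_coeffs: np.ndarray
    bias_coeffs: np.ndarray
    in_basis: BasisSystem
    out_basis: BasisSystem
    activation: str = "tanh"


def build_variant_function(values, positions_bp, modality_id: str = "omics") -> OmicsVariantFunction:
    """Min-max rescale base-pair positions to [0, 1] and wrap the marker matrix.

    A single-marker modality is placed at t = 0.5 by convention.  Duplicate or
    unsorted positions are rejected: silently jittering ties would hide data
    problems upstream.
    """
    values = np.asarray(values, dtype=float)
    pos = np.asarray(positions_bp, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (samples x markers) matrix")
    if pos.ndim != 1 or pos.size != values.shape[1]:
        raise ValueError(
            f"positions length ({pos.size}) must match marker count ({values.shape[1]})"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("marker values must be finite")
    if pos.size == 1:
        return OmicsVariantFunction(values, np.array([0.5]), modality_id)
    d = np.diff(pos)
    if np.any(d == 0):
        idx = np.flatnonzero(d == 0)
        raise DuplicatePositionError(
            f"duplicate marker positions at indices {idx.tolist()} "
            f"(bp {pos[idx].astype(int).tolist()})"
        )
    if np.any(d < 0):
        raise ValueError("positions must be sorted ascending")
    positions01 = (pos - pos[0]) / (pos[-1] - pos[0])
    return OmicsVariantFunction(values, positions01, modality_id)


def dirac_design(ovf: OmicsVariantFunction, basis: BasisSystem) -> np.ndarray:
    """Exact design matrix Phi[i, l] = int G_i(t) eta_l(t) dt = sum_j g_ij eta_l(t_j).

    The Dirac-comb representation makes this a plain matrix product against
    the basis evaluated at the marker positions; no quadrature is involved.
    """
    B = eval_basis(basis, ovf.positions01)  # (p, J)
    return ovf.values @ B


# ---------------------------------------------------------------------------
# trainable layers with explicit reverse-mode derivatives
# ---------------------------------------------------------------------------

@dataclass
class Param:
    name: str
    value: np.ndarray
    penalized: bool = True  # weights are penalized, biases are not
    grad: np.ndarray = field(default=None, repr=False)

    def zero_grad(self):
        self.grad = np.zeros_like(self.value)


class FunctionalFirstLayer:
    """Z^(1)_i(t_m) = sigma( X_i alpha + [Phi W eta_out(t_m)]_i ).

    Follows the first-layer equation literally: a covariate term plus the
    integral of the Dirac comb against beta^(1), and no functional bias.
    The marker design Phi is supplied at call time (it is data, not a
    parameter); ``E_out`` = eta_out evaluated on the grid is fixed.
    """

    def __init__(self, in_basis: BasisSystem, out_basis: BasisSystem,
                 grid: QuadratureGrid, activation: str = "tanh",
                 n_covariates: int = 0, rng: np.random.Generator | None = None,
                 name: str = "first"):
        self.in_basis = in_basis
        self.out_basis = out_basis
        self.grid = grid
        self.activation = activation
        self.E_out = eval_basis(out_basis, grid.points)  # (M, J_out)
        rng = rng or np.random.default_rng(0)
        J_in, J_out = in_basis.n_basis, out_basis.n_basis
        self.W = Param(f"{name}.W", glorot(rng, J_in, J_out), penalized=True)
        self.alpha = Param(f"{name}.alpha", np.zeros(n_covariates), penalized=True)
        self._cache = None

    @property
    def params(self):
        ps = [self.W]
        if self.alpha.value.size:
            ps.append(self.alpha)
        return ps

    def forward(self, Phi: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
        f, _ = get_activation(self.activation)
        pre = Phi @ self.W.value @ self.E_out.T
        if X is not None and X.shape[1] and self.alpha.value.size:
            pre = pre + (X @ self.alpha.value)[:, None]
        out = f(pre)
        self._cache = (Phi, X, pre, out)
        return out

    def backward(self, dout: np.ndarray) -> None:
        Phi, X, pre, out = self._cache
        _, df = get_activation(self.activation)
        dpre = dout * df(pre, out)
        self.W.grad += Phi.T @ dpre @ self.E_out
        if X is not None and X.shape[1] and self.alpha.value.size:
            self.alpha.grad += X.T @ dpre.sum(axis=1)
        # gradient w.r.t. the data is never needed


class FunctionalHiddenLayer:
    """Z^(d)_i(t_m) = sigma( alpha0(t_m) + int Z^(d-1)_i(s) beta(t_m, s) ds ).

    Discretized: U = (Z * q) E_in collapses the s-integral, then
    pre = U W E_out^T + (E_out b)^T.
    """

    def __init__(self, in_basis: BasisSystem, out_basis: BasisSystem,
                 grid: QuadratureGrid, activation: str = "tanh",
                 rng: np.random.Generator | None = None, name: str = "hidden"):
        self.in_basis = in_basis
        self.out_basis = out_basis
        self.grid = grid
        self.activation = activation
        self.E_in = eval_basis(in_basis, grid.points)    # (M, J_in)
        self.E_out = eval_basis(out_basis, grid.points)  # (M, J_out)
        rng = rng or np.random.default_rng(0)
        J_in, J_out = in_basis.n_basis, out_basis.n_basis
        self.W = Param(f"{name}.W", glorot(rng, J_in, J_out), penalized=True)
        self.b = Param(f"{name}.b", np.zeros(J_out), penalized=False)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, Z: np.ndarray) -> np.ndarray:
        f, _ = get_activation(self.activation)
        U = (Z * self.grid.weights) @ self.E_in            # (n, J_in)
        pre = U @ self.W.value @ self.E_out.T + (self.E_out @ self.b.value)[None, :]
        out = f(pre)
        self._cache = (Z, U, pre, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        Z, U, pre, out = self._cache
        _, df = get_activation(self.activation)
        dpre = dout * df(pre, out)
        dE = dpre @ self.E_out                              # (n, J_out)
        self.W.grad += U.T @ dE
        self.b.grad += dpre.sum(axis=0) @ self.E_out
        dU = dE @ self.W.value.T
        return (dU @ self.E_in.T) * self.grid.weights


class FunctionalOutputLayer:
    """Z^(D)_iu = f( b_u + int Z^(D-1)_i(s) beta_u(s) ds ); identity link."""

    def __init__(self, in_basis: BasisSystem, grid: QuadratureGrid, width: int,
                 rng: np.random.Generator | None = None, name: str = "out"):
        self.in_basis = in_basis
        self.grid = grid
        self.width = width
        self.E_in = eval_basis(in_basis, grid.points)  # (M, J_in)
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{name}.W", glorot(rng, in_basis.n_basis, width), penalized=True)
        self.b = Param(f"{name}.b", np.zeros(width), penalized=False)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, Z: np.ndarray) -> np.ndarray:
        U = (Z * self.grid.weights) @ self.E_in
        out = U @ self.W.value + self.b.value[None, :]
        self._cache = (Z, U)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        Z, U = self._cache
        self.W.grad += U.T @ dout
        self.b.grad += dout.sum(axis=0)
        dU = dout @ self.W.value.T
        return (dU @ self.E_in.T) * self.grid.weights


class DenseLayer:
    """Plain affine layer out = sigma(X W + b); the degenerate (linear-basis) path."""

    def __init__(self, n_in: int, n_out: int, activation: str = "identity",
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.W = Param(f"{name}.W", glorot(rng, n_in, n_out), penalized=True)
        self.b = Param(f"{name}.b", np.zeros(n_out), penalized=False)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        f, _ = get_activation(self.activation)
        pre = X @ self.W.value + self.b.value[None, :]
        out = f(pre)
        self._cache = (X, pre, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        X, pre, out = self._cache
        _, df = get_activation(self.activation)
        dpre = dout * df(pre, out)
        self.W.grad += X.T @ dpre
        self.b.grad += dpre.sum(axis=0)
        return dpre @ self.W.value.T


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# ---------------------------------------------------------------------------
# stateless forward operations (thin wrappers over the layer classes)
# ---------------------------------------------------------------------------

def first_layer_forward(ovf: OmicsVariantFunction, params: FunctionalLayerParams,
                        cov: CovariateBlock | None, grid: QuadratureGrid) -> HiddenFunction:
    """Forward the first functional layer for given fixed parameters."""
    layer = FunctionalFirstLayer(params.in_basis, params.out_basis, grid,
                                 activation=params.activation,
                                 n_covariates=0 if cov is None else cov.X.shape[1])
    layer.W.value = np.asarray(params.weight_coeffs, dtype=float)
    _check_shape(layer.W.value, (params.in_basis.n_basis, params.out_basis.n_basis), "weight_coeffs")
    Phi = dirac_design(ovf, params.in_basis)
    X = None
    if cov is not None and cov.X.shape[1]:
        layer.alpha.value = np.asarray(cov.alpha, dtype=float)
        X = cov.X
    return HiddenFunction(grid=grid, values=layer.forward(Phi, X))


def hidden_layer_forward(Z_prev: HiddenFunction, params: FunctionalLayerParams) -> HiddenFunction:
    layer = FunctionalHiddenLayer(params.in_basis, params.out_basis, Z_prev.grid,
                                  activation=params.activation)
    layer.W.value = np.asarray(params.weight_coeffs, dtype=float)
    layer.b.value = np.asarray(params.bias_coeffs, dtype=float)
    _check_shape(layer.W.value, (params.in_basis.n_basis, params.out_basis.n_basis), "weight_coeffs")
    _check_shape(layer.b.value, (params.out_basis.n_basis,), "bias_coeffs")
    return HiddenFunction(grid=Z_prev.grid, values=layer.forward(Z_prev.values))


def output_layer_forward(Z_prev: HiddenFunction, in_basis: BasisSystem,
                         weight_funcs: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Integrate the last hidden function against per-unit weight functions."""
    weight_funcs = np.asarray(weight_funcs, dtype=float)
    biases = np.asarray(biases, dtype=float)
    q = weight_funcs.shape[1]
    layer = FunctionalOutputLayer(in_basis, Z_prev.grid, q)
    layer.W.value = weight_funcs
    layer.b.value = biases
    _check_shape(weight_funcs, (in_basis.n_basis, q), "weight_funcs")
    _check_shape(biases, (q,), "biases")
    return layer.forward(Z_prev.values)


def _check_shape(arr: np.ndarray, shape: tuple, what: str) -> None:
    if arr.shape != shape:
        raise ValueError(f"{what} has shape {arr.shape}, expected {shape}")
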