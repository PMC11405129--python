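"""Comparison methods: the functional linear model, a plain feedforward NN,
and a single functional network on concatenated inputs (FNN-3HL).

The FLM treats each functional modality through its exact Dirac design in a
fixed basis and is fitted in closed form as a ridge problem — the honest
linear baseline, not an iterative approximation.  The NN baseline ignores
positional structure entirely (raw columns concatenated); FNN-3HL keeps the
functional machinery but forces all modalities onto one artificial [0, 1]
axis with uniform pseudo-positions, which is exactly what a single-input
functional network must do with multiomics data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSystem, make_bspline_system, uniform_grid, DEFAULT_GRID_SIZE
from .functional import (
    DenseLayer,
    FunctionalFirstLayer,
    FunctionalHiddenLayer,
    FunctionalOutputLayer,
    OmicsVariantFunction,
    dirac_design,
)
from .training import FitSchedule, LossSpec, TrainingData, fit

__all__ = [
    "FLMModel",
    "fit_flm",
    "predict_flm",
    "DenseNN",
    "fit_nn",
    "FNN3HL",
    "fit_fnn3hl",
    "concat_raw",
    "concat_pseudo_modality",
]


# ---------------------------------------------------------------------------
# functional linear model (closed-form ridge)
# ---------------------------------------------------------------------------

class SingularDesignError(np.linalg.LinAlgError):
    pass


@dataclass
class FLMModel:
    """Ridge-fitted scalar-on-function linear model.

    ``coef`` stacks [intercept | covariates | basis scores per modality]
    (columns of the phenotype if it is a vector); ``slices`` records the
    column block of each term.
    """

    coef: np.ndarray
    slices: dict
    bases: list
    ridge_lambda: float

    def beta_function(self, k: int, t) -> np.ndarray:
        """Evaluate the functional effect beta_k(t) of modality k."""
        basis = self.bases[k]
        if basis is None:
            raise ValueError(f"modality {k} entered as raw columns, not functional")
        block = self.coef[self.slices[f"modality{k}"]]
        return basis.eval(np.atleast_1d(t)) @ block


def _flm_design(modalities, covariates, bases):
    blocks = [np.ones((_n(modalities[0]), 1))]
    slices = {"intercept": slice(0, 1)}
    col = 1
    if covariates is not None and covariates.shape[1]:
        blocks.append(covariates)
        slices["covariates"] = slice(col, col + covariates.shape[1])
        col += covariates.shape[1]
    for k, m in enumerate(modalities):
        if isinstance(m, OmicsVariantFunction):
            Phi = dirac_design(m, bases[k])
        else:
            Phi = np.asarray(m, dtype=float)
        blocks.append(Phi)
        slices[f"modality{k}"] = slice(col, col + Phi.shape[1])
        col += Phi.shape[1]
    return np.concatenate(blocks, axis=1), slices


def _n(m):
    return m.values.shape[0] if isinstance(m, OmicsVariantFunction) else np.asarray(m).shape[0]


def fit_flm(modalities, covariates, y, bases=None, ridge_lambda: float = 0.1) -> FLMModel:
    """Closed-form ridge fit of the functional linear model.

    Minimizes (1/n)||y - A beta||^2 + (lambda/2) |beta_pen|^2 where the
    intercept and covariate columns are unpenalized, i.e. solves
    (A'A + (n lambda / 2) P) beta = A'y.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1 and y.shape[1] > 1:
        y = y.T
    if bases is None:
        bases = [make_bspline_system() if isinstance(m, OmicsVariantFunction) else None
                 for m in modalities]
    A, slices = _flm_design(modalities, covariates, bases)
    n, p = A.shape
    P = np.ones(p)
    P[slices["intercept"]] = 0.0
    if "covariates" in slices:
        P[slices["covariates"]] = 0.0
    lhs = A.T @ A + (n * ridge_lambda / 2.0) * np.diag(P)
    try:
        coef = np.linalg.solve(lhs, A.T @ y)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "normal equations are singular; set ridge_lambda > 0 "
            "(collinear or empty design columns)") from exc
    return FLMModel(coef=coef, slices=slices, bases=bases, ridge_lambda=ridge_lambda)


def predict_flm(model: FLMModel, modalities, covariates=None) -> np.ndarray:
    A, _ = _flm_design(modalities, covariates, model.bases)
    return A @ model.coef


def flm_objective(model: FLMModel, modalities, covariates, y) -> float:
    """The regularized training objective attained by the closed-form fit."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1 and y.shape[1] > 1:
        y = y.T
    y_hat = predict_flm(model, modalities, covariates)
    n = y.shape[0]
    J = float(np.sum((y - y_hat) ** 2) / n)
    pen = np.ones(model.coef.shape[0])
    pen[model.slices["intercept"]] = 0.0
    if "covariates" in model.slices:
        pen[model.slices["covariates"]] = 0.0
    return J + model.ridge_lambda * 0.5 * float(np.sum(pen[:, None] * model.coef ** 2))


# ---------------------------------------------------------------------------
# plain feedforward NN on concatenated raw inputs
# ---------------------------------------------------------------------------

def concat_raw(modalities) -> np.ndarray:
    """Column-wise concatenation of raw modality matrices (positions ignored)."""
    cols = [m.values if isinstance(m, OmicsVariantFunction) else np.asarray(m, dtype=float)
            for m in modalities]
    return np.concatenate(cols, axis=1)


class DenseNN:
    """A plain feedforward network with the MFDL training interface."""

    def __init__(self, n_in: int, hidden_widths, output_dim: int,
                 activation: str = "tanh", seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = [n_in, *hidden_widths]
        self.layers = [
            DenseLayer(widths[i], widths[i + 1], activation=activation, rng=rng,
                       name=f"nn.L{i + 1}")
            for i in range(len(widths) - 1)
        ]
        self.layers.append(DenseLayer(widths[-1], output_dim, activation="identity",
                                      rng=rng, name="nn.out"))
        self.rng_seed = seed

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def forward(self, modalities, covariates=None) -> np.ndarray:
        X = modalities[0] if len(modalities) == 1 else concat_raw(modalities)
        if isinstance(X, OmicsVariantFunction):
            X = X.values
        Z = np.asarray(X, dtype=float)
        for layer in self.layers:
            Z = layer.forward(Z)
        return Z

    def backward(self, d_yhat: np.ndarray) -> None:
        d = d_yhat
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict(self, modalities, covariates=None):
        return self.forward(modalities, covariates)


def fit_nn(X: np.ndarray, y: np.ndarray, hidden_widths=(16,), ridge_lambda: float = 0.1,
           schedule: FitSchedule | None = None, seed: int = 0,
           activation: str = "tanh"):
    """Train the dense baseline with the shared loss/optimizer stack."""
    y2 = np.atleast_2d(np.asarray(y, dtype=float))
    if y2.shape[0] == 1 and y2.shape[1] > 1:
        y2 = y2.T
    model = DenseNN(np.asarray(X).shape[1], hidden_widths, y2.shape[1],
                    activation=activation, seed=seed)
    model, history = fit(model, TrainingData(modalities=[X], y=y2),
                         LossSpec(ridge_lambda), schedule)
    return model, history


# ---------------------------------------------------------------------------
# FNN-3HL: one functional network on concatenated discretized inputs
# ---------------------------------------------------------------------------

def concat_pseudo_modality(modalities) -> OmicsVariantFunction:
    """Merge all modalities onto one [0, 1] axis with uniform pseudo-positions."""
    X = concat_raw(modalities)
    p = X.shape[1]
    pos = np.array([0.5]) if p == 1 else np.linspace(0.0, 1.0, p)
    return OmicsVariantFunction(values=X, positions01=pos, modality_id="concat")


class FNN3HL:
    """Single functional subnet with three hidden layers mapping to the phenotype."""

    n_hidden_layers = 3

    def __init__(self, output_dim: int, marker_basis=(5, 7), layer_basis=(5, 7),
                 grid_size: int = DEFAULT_GRID_SIZE, activation: str = "tanh",
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        mb = make_bspline_system(*marker_basis)
        lb = make_bspline_system(*layer_basis)
        grid = uniform_grid(grid_size)
        self.marker_basis = mb
        self.layers = [
            FunctionalFirstLayer(mb, lb, grid, activation=activation, rng=rng,
                                 name="fnn.L1"),
            FunctionalHiddenLayer(lb, lb, grid, activation=activation, rng=rng,
                                  name="fnn.L2"),
            FunctionalHiddenLayer(lb, lb, grid, activation=activation, rng=rng,
                                  name="fnn.L3"),
            FunctionalOutputLayer(lb, grid, output_dim, rng=rng, name="fnn.out"),
        ]
        self.rng_seed = seed

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def forward(self, modalities, covariates=None) -> np.ndarray:
        ovf = modalities[0] if (len(modalities) == 1
                                and isinstance(modalities[0], OmicsVariantFunction)) \
            else concat_pseudo_modality(modalities)
        key = tuple(m.values if isinstance(m, OmicsVariantFunction) else m
                    for m in modalities)
        cached = getattr(self, "_phi_cache", None)
        if cached is not None and len(cached[0]) == len(key) and all(
                a is b for a, b in zip(cached[0], key)):
            Phi = cached[1]
        else:
            Phi = dirac_design(ovf, self.marker_basis)
            self._phi_cache = (key, Phi)
        Z = self.layers[0].forward(Phi, None)
        for layer in self.layers[1:]:
            Z = layer.forward(Z)
        return Z

    def backward(self, d_yhat: np.ndarray) -> None:
        d = d_yhat
        for layer in reversed(self.layers[1:]):
            d = layer.backward(d)
        self.layers[0].backward(d)

    def predict(self, modalities, covariates=None):
        return self.forward(modalities, covariates)


def fit_fnn3hl(modalities, y, output_dim: int | None = None, ridge_lambda: float = 0.1,
               schedule: FitSchedule | None = None, seed: int = 0,
               activation: str = "tanh", **kwargs):
    """Train FNN-3HL on the concatenated pseudo-modality."""
    y2 = np.atleast_2d(np.asarray(y, dtype=float))
    if y2.shape[0] == 1 and y2.shape[1] > 1:
        y2 = y2.T
    pseudo = concat_pseudo_modality(modalities)
    model = FNN3HL(output_dim or y2.shape[1], activation=activation, seed=seed, **kwargs)
    model, history = fit(model, TrainingData(modalities=[pseudo], y=y2),
                         LossSpec(ridge_lambda), schedule)
    return model, history
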