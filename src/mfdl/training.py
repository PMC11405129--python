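"""Regularized loss, exact gradients, ADADELTA updates, and the fit loop.

The objective is the ridge-regularized mean squared error

    J~(W, b) = (1/n) sum_i ||y_i - yhat_i||^2 + (lambda/2) ||W||_2^2,

where W collects every weight array and biases are excluded from the
penalty.  Gradients are the exact reverse-mode derivatives of the
discretized forward pass (basis evaluations and quadrature weights are
constants), so the objective that is differentiated is the one actually
minimized.  Parameters are updated full-batch with per-parameter adaptive
step sizes (ADADELTA): decaying accumulators of squared gradients and
squared updates, no global learning rate to tune.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MFDLModel

__all__ = [
    "LossSpec",
    "AdadeltaState",
    "FitSchedule",
    "TrainingData",
    "loss",
    "gradients",
    "adadelta_step",
    "fit",
    "select_lambda",
]


class DivergenceError(RuntimeError):
    pass


@dataclass
class LossSpec:
    lambda_penalty: float = 0.0
    includes_bias_in_penalty: bool = False  # Omega(W) covers weights only

    def __post_init__(self):
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")


@dataclass
class TrainingData:
    """One batch: modality inputs, optional covariates, phenotype matrix."""

    modalities: list
    y: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] == 1 and self.y.shape[1] > 1:
            self.y = self.y.T


@dataclass
class AdadeltaState:
    """Per-parameter accumulators E[g^2] and E[dx^2] (Zeiler's rule)."""

    rho: float = 0.95
    eps: float = 1e-6
    acc_grad_sq: dict = field(default_factory=dict)
    acc_update_sq: dict = field(default_factory=dict)

    def _ensure(self, name: str, like: np.ndarray):
        if name not in self.acc_grad_sq:
            self.acc_grad_sq[name] = np.zeros_like(like)
            self.acc_update_sq[name] = np.zeros_like(like)


@dataclass
class FitSchedule:
    """Loop control.  ``optimizer`` is "adadelta" (default) or "gd", a plain
    fixed-step gradient-descent reference mode."""

    max_epochs: int = 10**5
    convergence_tol: float = 1e-6   # relative J~ change
    patience: int = 50              # epochs the tolerance must hold
    optimizer: str = "adadelta"
    learning_rate: float = 0.05     # used by the "gd" mode only

    def __post_init__(self):
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.optimizer not in ("adadelta", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def loss(y: np.ndarray, y_hat: np.ndarray, params, spec: LossSpec) -> tuple[float, float]:
    """Return (J, J~): empirical risk and its ridge-regularized version."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    n = y.shape[0]
    J = float(np.sum((y - y_hat) ** 2) / n)
    pen = sum(float(np.sum(p.value ** 2)) for p in params
              if p.penalized or spec.includes_bias_in_penalty)
    return J, J + spec.lambda_penalty * 0.5 * pen


def gradients(model: MFDLModel, modalities, covariates, y, spec: LossSpec) -> dict:
    """Exact gradients of J~ w.r.t. every parameter; returns {name: array}.

    The penalty contributes lambda * W to weight gradients and nothing to
    bias gradients.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    model.zero_grad()
    y_hat = model.forward(modalities, covariates)
    if not np.all(np.isfinite(y_hat)):
        raise DivergenceError("non-finite values in the forward pass")
    n = y.shape[0]
    model.backward(2.0 / n * (y_hat - y))
    out = {}
    for p in model.params:
        g = p.grad
        if p.penalized and spec.lambda_penalty:
            g = g + spec.lambda_penalty * p.value
        out[p.name] = g
    return out


def adadelta_step(state: AdadeltaState, params, grads: dict) -> None:
    """Apply one ADADELTA update in place.

    E[g^2] <- rho E[g^2] + (1-rho) g^2
    dx      = -sqrt(E[dx^2] + eps) / sqrt(E[g^2] + eps) * g
    E[dx^2] <- rho E[dx^2] + (1-rho) dx^2
    """
    rho, eps = state.rho, state.eps
    for p in params:
        g = grads[p.name]
        state._ensure(p.name, p.value)
        Eg = state.acc_grad_sq[p.name]
        Ed = state.acc_update_sq[p.name]
        Eg *= rho
        Eg += (1 - rho) * g * g
        dx = -np.sqrt(Ed + eps) / np.sqrt(Eg + eps) * g
        Ed *= rho
        Ed += (1 - rho) * dx * dx
        p.value = p.value + dx


def fit(model: MFDLModel, data: TrainingData, spec: LossSpec | None = None,
        schedule: FitSchedule | None = None) -> tuple[MFDLModel, pd.DataFrame]:
    """Full-batch training loop: forward -> gradients -> ADADELTA update.

    Stops when the relative J~ improvement stays below ``convergence_tol``
    for ``patience`` consecutive epochs, or at ``max_epochs``.  Returns the
    trained model (updated in place) and a per-epoch history frame with
    columns epoch, J, J_tilde, grad_norm.
    """
    spec = spec or LossSpec()
    schedule = schedule or FitSchedule()
    state = AdadeltaState()
    hist = {"epoch": [], "J": [], "J_tilde": [], "grad_norm": []}
    prev = None
    stall = 0
    n = data.y.shape[0]
    for epoch in range(schedule.max_epochs):
        # one forward pass per epoch: reuse it for the loss and the gradients
        model.zero_grad()
        y_hat = model.forward(data.modalities, data.covariates)
        if not np.all(np.isfinite(y_hat)):
            raise DivergenceError(f"non-finite forward values at epoch {epoch}")
        model.backward(2.0 / n * (y_hat - data.y))
        grads = {}
        for p in model.params:
            g = p.grad
            if p.penalized and spec.lambda_penalty:
                g = g + spec.lambda_penalty * p.value
            grads[p.name] = g
        J, Jt = loss(data.y, y_hat, model.params, spec)
        if not np.isfinite(Jt):
            raise DivergenceError(f"objective became non-finite at epoch {epoch}")
        gnorm = float(np.sqrt(sum(np.sum(g * g) for g in grads.values())))
        hist["epoch"].append(epoch)
        hist["J"].append(J)
        hist["J_tilde"].append(Jt)
        hist["grad_norm"].append(gnorm)
        if schedule.optimizer == "adadelta":
            adadelta_step(state, model.params, grads)
        else:
            for p in model.params:
                p.value = p.value - schedule.learning_rate * grads[p.name]
        if prev is not None:
            rel = abs(prev - Jt) / max(abs(prev), 1e-12)
            stall = stall + 1 if rel < schedule.convergence_tol else 0
            if stall >= schedule.patience:
                break
        prev = Jt
    return model, pd.DataFrame(hist)


def select_lambda(model_factory, data: TrainingData, grid, seed: int = 0,
                  mode: str = "split", schedule: FitSchedule | None = None,
                  val_fraction: float = 0.25) -> tuple[float, pd.DataFrame]:
    """Pick the ridge penalty from a grid by validation MSE.

    ``model_factory(seed)`` must return a fresh model.  ``mode="split"``
    holds out ``val_fraction`` of the samples once; ``mode="cv3"`` averages
    validation MSE over a 3-fold partition.  Ties break toward the larger
    (more conservative) penalty.  Returns the chosen lambda and the table of
    per-lambda validation errors.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    rng = np.random.default_rng(seed)
    n = data.y.shape[0]
    perm = rng.permutation(n)
    if mode == "split":
        n_val = max(1, int(round(val_fraction * n)))
        folds = [(perm[n_val:], perm[:n_val])]
    elif mode == "cv3":
        parts = np.array_split(perm, 3)
        folds = [(np.concatenate([parts[j] for j in range(3) if j != i]), parts[i])
                 for i in range(3)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for lam in grid:
        errs = []
        for tr, va in folds:
            model = model_factory(seed)
            fit(model, _subset(data, tr), LossSpec(lambda_penalty=lam), schedule)
            y_hat = model.forward(_subset_modalities(data.modalities, va),
                                  None if data.covariates is None else data.covariates[va])
            errs.append(float(np.mean(np.sum((data.y[va] - y_hat) ** 2, axis=1))))
        rows.append({"lambda": lam, "val_mse": float(np.mean(errs))})
    table = pd.DataFrame(rows)
    best = table["val_mse"].min()
    chosen = max(t["lambda"] for t in rows if t["val_mse"] <= best + 1e-15)
    return chosen, table


def _subset_modalities(modalities, idx):
    from .functional import OmicsVariantFunction

    out = []
    for m in modalities:
        if isinstance(m, OmicsVariantFunction):
            out.append(OmicsVariantFunction(m.values[idx], m.positions01, m.modality_id))
        else:
            out.append(np.asarray(m)[idx])
    return out


def _subset(data: TrainingData, idx) -> TrainingData:
    return TrainingData(
        modalities=_subset_modalities(data.modalities, idx),
        y=data.y[idx],
        covariates=None if data.covariates is None else data.covariates[idx],
    )
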