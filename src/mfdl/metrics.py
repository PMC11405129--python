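"""Evaluation metrics: MSE, MAE, and the RV correlation coefficient.

MSE is the per-sample squared prediction error averaged over samples (for a
vector phenotype the squared Euclidean norm of the residual row).  The RV
coefficient of Robert and Escoufier is the multivariate generalization of
the squared Pearson correlation,

    RV(Y, Yhat) = tr(Y Y' Yhat Yhat') / sqrt( tr((Y Y')^2) tr((Yhat Yhat')^2) ),

computed on column-mean-centered matrices; centering makes the single-column
case coincide with the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["mse", "mae", "rv_coefficient", "EvalResult", "results_to_frame"]


class DegenerateRVError(ValueError):
    """Raised when an input matrix is constant (zero after centering)."""


def _as2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def mse(Y, Y_hat) -> float:
    Y, Y_hat = _as2d(Y), _as2d(Y_hat)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Y_hat.shape}")
    return float(np.sum((Y - Y_hat) ** 2) / Y.shape[0])


def mae(Y, Y_hat) -> float:
    Y, Y_hat = _as2d(Y), _as2d(Y_hat)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Y_hat.shape}")
    return float(np.mean(np.abs(Y - Y_hat)))


def rv_coefficient(Y, Y_hat) -> float:
    """RV coefficient in [0, 1] between two centered configurations.

    With G = Yc Yc' and H = Yhc Yhc' (Gram matrices of the centered inputs),
    RV = tr(GH) / sqrt(tr(G^2) tr(H^2)); both traces are sums of squared
    Gram entries, hence nonnegative, and Cauchy-Schwarz bounds RV by 1.
    """
    Y, Y_hat = _as2d(Y), _as2d(Y_hat)
    if Y.shape[0] != Y_hat.shape[0]:
        raise ValueError(f"row counts differ: {Y.shape[0]} vs {Y_hat.shape[0]}")
    Yc = Y - Y.mean(axis=0)
    Hc = Y_hat - Y_hat.mean(axis=0)
    G = Yc @ Yc.T
    H = Hc @ Hc.T
    tr_g2 = float(np.sum(G * G))
    tr_h2 = float(np.sum(H * H))
    if tr_g2 <= 0 or tr_h2 <= 0:
        raise DegenerateRVError(
            "RV undefined: an input is constant (all-zero after centering)")
    return float(np.sum(G * H) / np.sqrt(tr_g2 * tr_h2))


@dataclass
class EvalResult:
    """One method's metrics on one split of one replicate."""

    method: str
    split: str          # "train" | "test"
    mse: float
    mae: float
    rv: float
    n: int
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.mse < 0 or self.mae < 0:
            raise ValueError("mse and mae must be nonnegative")


def results_to_frame(results) -> pd.DataFrame:
    """Serialize EvalResult rows to a tidy frame (one row per result)."""
    return pd.DataFrame([asdict(r) for r in results])


def evaluate(method: str, split: str, Y, Y_hat, replicate_id: int = 0,
             seed: int = 0) -> EvalResult:
    """Compute all three metrics at once for a (Y, Yhat) pair."""
    return EvalResult(
        method=method, split=split,
        mse=mse(Y, Y_hat), mae=mae(Y, Y_hat), rv=rv_coefficient(Y, Y_hat),
        n=_as2d(Y).shape[0], replicate_id=replicate_id, seed=seed,
    )
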