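"""Stacked ensemble: a Poisson GLM over the base models' log-predictions.

The stacker regresses the observed flows ``y_k`` (vectorised off-diagonal
OD cells) on the logs of the five base-model predictions::

    log(mu_k) = b0 + b1 log(l_1k) + b2 log(l_2k) + ... + b5 log(l_5k)

with a log link and Poisson variance, fitted by iteratively reweighted
least squares (IRLS).  Column order is fixed: gravity, gravity_distance,
radiation, radiation_selection, intervening_opportunities.  Collinear
columns are kept — near-duplicate base predictions legitimately produce
huge offsetting weights whose information content cancels — and
near-singular IRLS steps are solved with a pseudo-inverse (an optional
ridge penalty is available for stability).  Diagonal cells carry no
information (base predictions there are identically zero) and are
excluded from both fitting and prediction; ensemble predictions keep a
zero diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy

from .errors import InvalidInputError
from .models import MODEL_IDS, PREDICTION_FLOOR, ODMatrix

logger = logging.getLogger("flowstack")

#: Cap applied to ensemble predictions when exp() would overflow.
MAX_PREDICTION = 1e15


@dataclass(frozen=True)
class EnsembleConfig:
    max_iter: int = 200
    tol: float = 1e-10   # relative deviance change at convergence
    ridge: float = 0.0   # optional L2 penalty on the five weights (not b0)


@dataclass(frozen=True)
class StackedEnsemble:
    """Fitted stacker: intercept plus one weight per base model."""

    intercept: float
    weights: dict          # model id -> coefficient, in MODEL_IDS order
    converged: bool
    training_deviance: float
    n_iterations: int

    def __post_init__(self):
        if tuple(self.weights) != MODEL_IDS:
            raise InvalidInputError("ensemble weights must be keyed by the five model ids in order")

    @property
    def coefficients(self) -> np.ndarray:
        """``[b0, b1..b5]`` in fixed model order."""
        return np.array([self.intercept] + [self.weights[m] for m in MODEL_IDS])

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "weights": dict(self.weights),
            "converged": self.converged,
            "training_deviance": self.training_deviance,
        }


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # Poisson deviance with the y=0 limit y log y -> 0; mu already floored.
    return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))


def build_design(predictions: Sequence[ODMatrix]):
    """Design matrix of log base-model predictions.

    Returns ``(X, cells)`` where ``X`` has one row per off-diagonal cell and
    one column per base model (``log(max(prediction, 1e-10))``), and
    ``cells`` is the ``(k, 2)`` array of (origin, destination) indices in
    row-major order for reassembling vectors into matrices.
    """
    if len(predictions) != len(MODEL_IDS):
        raise InvalidInputError(f"expected {len(MODEL_IDS)} base predictions, got {len(predictions)}")
    n = predictions[0].n
    ids = predictions[0].ids
    for p in predictions:
        if p.n != n or p.ids != ids:
            raise InvalidInputError("base predictions are not aligned to the same regions")
    off = ~np.eye(n, dtype=bool)
    cells = np.argwhere(off)
    X = np.column_stack(
        [np.log(np.maximum(p.values[off], PREDICTION_FLOOR)) for p in predictions]
    )
    return X, cells


def fit_ensemble(
    observed: ODMatrix,
    predictions: Sequence[ODMatrix],
    config: Optional[EnsembleConfig] = None,
    train_mask: Optional[np.ndarray] = None,
) -> StackedEnsemble:
    """Fit the Poisson stacker by IRLS.

    ``train_mask`` restricts fitting to the marked off-diagonal cells
    (cross-validation holds out the rest).  Divergence is reported via
    ``converged=False`` with a warning, never silently.
    """
    cfg = config or EnsembleConfig()
    X, cells = build_design(predictions)
    if observed.n != predictions[0].n or observed.ids != predictions[0].ids:
        raise InvalidInputError("observed matrix is not aligned with the base predictions")
    sel = np.ones(len(cells), dtype=bool)
    if train_mask is not None:
        train_mask = np.asarray(train_mask, bool)
        sel = train_mask[cells[:, 0], cells[:, 1]]
    y = observed.values[cells[:, 0], cells[:, 1]][sel]
    Xd = np.column_stack([np.ones(sel.sum()), X[sel]])

    penalty = cfg.ridge * np.diag([0.0] + [1.0] * len(MODEL_IDS))
    beta = np.zeros(Xd.shape[1])
    beta[0] = np.log(max(y.mean(), PREDICTION_FLOOR))  # intercept-only start

    def mu_of(b):
        eta = np.clip(Xd @ b, -700.0, 700.0)
        return np.maximum(np.exp(eta), PREDICTION_FLOOR)

    mu = mu_of(beta)
    dev = _deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        eta = np.log(mu)
        z = eta + (y - mu) / mu
        W = mu
        A = Xd.T @ (W[:, None] * Xd) + penalty
        b_vec = Xd.T @ (W * z)
        beta_new = np.linalg.pinv(A) @ b_vec
        # step-halve if the Fisher step overshoots
        step = beta_new - beta
        for _ in range(40):
            cand = beta + step
            dev_new = _deviance(y, mu_of(cand))
            if np.isfinite(dev_new) and dev_new <= dev + 1e-12 * (1 + abs(dev)):
                break
            step /= 2.0
        else:
            logger.warning("IRLS step could not reduce the deviance; stopping")
            break
        beta = beta + step
        mu = mu_of(beta)
        old, dev = dev, dev_new
        if abs(old - dev) <= cfg.tol * (abs(dev) + 0.1):
            converged = True
            break
    if not converged:
        logger.warning("ensemble IRLS did not converge in %d iterations (deviance %.6g)", it, dev)
    weights = {m: float(beta[a + 1]) for a, m in enumerate(MODEL_IDS)}
    return StackedEnsemble(
        intercept=float(beta[0]),
        weights=weights,
        converged=converged,
        training_deviance=float(dev),
        n_iterations=it,
    )


def predict_ensemble(model: StackedEnsemble, predictions: Sequence[ODMatrix]) -> ODMatrix:
    """Ensemble OD prediction ``mu = exp(b0 + sum_a b_a log l_a)`` on
    off-diagonal cells; diagonal forced to zero.  Entries whose linear
    predictor overflows are capped at 1e15 with a warning."""
    X, cells = build_design(predictions)
    eta = model.intercept + X @ np.array([model.weights[m] for m in MODEL_IDS])
    with np.errstate(over="ignore", under="ignore"):
        mu = np.exp(eta)
    if np.any(~np.isfinite(mu)) or np.any(mu > MAX_PREDICTION):
        logger.warning("ensemble predictions overflowed; capping at %.1e", MAX_PREDICTION)
        mu = np.where(np.isfinite(mu), np.minimum(mu, MAX_PREDICTION), MAX_PREDICTION)
    n = predictions[0].n
    out = np.zeros((n, n))
    out[cells[:, 0], cells[:, 1]] = mu
    return ODMatrix(values=out, ids=predictions[0].ids)
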