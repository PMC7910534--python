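"""Poisson maximum-likelihood fitting of the base movement models.

Each model's parameters are estimated by minimising the Poisson negative
log-likelihood of the observed off-diagonal flows, using BFGS with
central-difference numerical gradients on an unconstrained
reparameterisation:

* ``log`` transform for positive scales and rates (θ, κ, the
  intervening-opportunities λ and exponent, the distance cut-off δ);
* ``logit`` transform for the selection λ, constrained to (0, 1);
* identity for the free exponents α, β, γ.

Observed flows may be non-integer (normalised GPS-like intensities): the
likelihood is the continuous-Poisson kernel ``Σ (μ − y log μ)``, dropping
the y-only ``log y!`` constant.  Zeros are treated as data; cells can be
excluded from the likelihood with an explicit mask (used by
cross-validation to hold out test cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, InvalidInputError
from .models import (
    MODEL_IDS,
    PREDICTION_FLOOR,
    GravityDistanceParams,
    GravityParams,
    InterveningOpportunitiesParams,
    ODMatrix,
    RadiationParams,
    RadiationSelectionParams,
    predict_matrix,
)
from .spatial import LocationSet, PairwiseGeometry

logger = logging.getLogger("flowstack")

_BIG = 1e300


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings.

    seed           — restart jitter stream (fitting is deterministic given it)
    max_iterations — BFGS iteration cap per start
    tolerance      — gradient-norm stopping tolerance
    max_restarts   — jittered restarts after a failed start
    fix_delta      — if set, freeze the gravity-with-distance cut-off at this
                     value (km) instead of fitting it
    """

    seed: int = 0
    max_iterations: int = 500
    tolerance: float = 1e-6
    max_restarts: int = 3
    fix_delta: Optional[float] = None


@dataclass(frozen=True)
class FitResult:
    model_id: str
    params: object
    neg_log_likelihood: float
    converged: bool
    n_iterations: int
    seed: int


def poisson_nll(observed: ODMatrix, predicted: ODMatrix, mask: Optional[np.ndarray] = None) -> float:
    """Poisson negative log-likelihood ``Σ (μ − y log μ)`` over off-diagonal
    cells (up to the y-only constant ``Σ log y!``).

    ``mask``, if given, further restricts the sum to cells where it is True
    (the diagonal is always excluded).  Predictions are floored at 1e-10
    before the logarithm.
    """
    y = observed.values if isinstance(observed, ODMatrix) else np.asarray(observed, float)
    mu = predicted.values if isinstance(predicted, ODMatrix) else np.asarray(predicted, float)
    if y.shape != mu.shape:
        raise InvalidInputError("observed and predicted matrices must have equal shape")
    if np.any(y < 0):
        raise InvalidInputError("observed flows must be non-negative")
    use = ~np.eye(y.shape[0], dtype=bool)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != y.shape:
            raise InvalidInputError("mask shape must match the matrices")
        use &= mask
    mu_c = np.maximum(mu[use], PREDICTION_FLOOR)
    yv = y[use]
    return float(np.sum(mu_c - yv * np.log(mu_c)))


# ---------------------------------------------------------------------------
# Unconstrained reparameterisation
# ---------------------------------------------------------------------------

def _logit(p):
    return np.log(p) - np.log1p(-p)

def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _pack(model_id: str, params, cfg: FitConfig) -> np.ndarray:
    if model_id == "gravity":
        return np.array([np.log(params.theta), params.alpha, params.beta, params.gamma])
    if model_id == "gravity_distance":
        x = []
        for p in (params.short, params.long):
            x += [np.log(p.theta), p.alpha, p.beta, p.gamma]
        if cfg.fix_delta is None:
            x.append(np.log(params.delta))
        return np.array(x)
    if model_id == "radiation":
        return np.array([np.log(params.theta)])
    if model_id == "radiation_selection":
        return np.array([np.log(params.theta), _logit(params.lam)])
    if model_id == "intervening_opportunities":
        return np.array([np.log(params.kappa), np.log(params.lam), np.log(params.theta_exp)])
    raise ConfigurationError(f"unknown model id {model_id!r}")


def _unpack(model_id: str, x: np.ndarray, cfg: FitConfig):
    if model_id == "gravity":
        return GravityParams(theta=np.exp(x[0]), alpha=x[1], beta=x[2], gamma=x[3])
    if model_id == "gravity_distance":
        short = GravityParams(theta=np.exp(x[0]), alpha=x[1], beta=x[2], gamma=x[3])
        long_ = GravityParams(theta=np.exp(x[4]), alpha=x[5], beta=x[6], gamma=x[7])
        delta = cfg.fix_delta if cfg.fix_delta is not None else np.exp(x[8])
        return GravityDistanceParams(delta=delta, short=short, long=long_)
    if model_id == "radiation":
        return RadiationParams(theta=np.exp(x[0]))
    if model_id == "radiation_selection":
        lam = float(np.clip(_expit(x[1]), 1e-12, 1 - 1e-12))
        return RadiationSelectionParams(theta=np.exp(x[0]), lam=lam)
    if model_id == "intervening_opportunities":
        return InterveningOpportunitiesParams(
            kappa=np.exp(x[0]), lam=np.exp(x[1]), theta_exp=np.exp(x[2])
        )
    raise ConfigurationError(f"unknown model id {model_id!r}")


def _start_params(model_id, observed, locs, geom, cfg, mask):
    """Data-driven starting values: unit exponents, scale matched to the
    observed mean flow, δ at the median distance, IO λ with a half-life at
    the median opportunity count."""
    off = ~np.eye(locs.n, dtype=bool)
    use = off if mask is None else (off & mask)
    ybar = float(observed.values[use].mean()) if use.any() else 0.0
    if ybar <= 0:
        logger.warning(
            "observed flows are all zero on the training cells; the fitted "
            "scale will collapse to the prediction floor"
        )
        ybar = PREDICTION_FLOOR

    def scale_for(unit_params):
        pred = predict_matrix(model_id, unit_params, locs, geom).values
        pbar = float(pred[use].mean())
        return ybar / max(pbar, PREDICTION_FLOOR)

    if model_id == "gravity":
        unit = GravityParams(theta=1.0, alpha=1.0, beta=1.0, gamma=1.0)
        return replace(unit, theta=scale_for(unit))
    if model_id == "gravity_distance":
        delta = cfg.fix_delta if cfg.fix_delta is not None else float(np.median(geom.distances[off]))
        g = GravityParams(theta=1.0, alpha=1.0, beta=1.0, gamma=1.0)
        unit = GravityDistanceParams(delta=delta, short=g, long=g)
        th = scale_for(unit)
        g = replace(g, theta=th)
        return GravityDistanceParams(delta=delta, short=g, long=g)
    if model_id == "radiation":
        unit = RadiationParams(theta=1.0)
        return RadiationParams(theta=scale_for(unit))
    if model_id == "radiation_selection":
        unit = RadiationSelectionParams(theta=1.0, lam=0.5)
        return RadiationSelectionParams(theta=scale_for(unit), lam=0.5)
    if model_id == "intervening_opportunities":
        m = np.broadcast_to(locs.populations[:, None], geom.distances.shape)
        med = float(np.median((geom.intervening + m)[off]))
        lam0 = np.log(2.0) / max(med, 1.0)
        unit = InterveningOpportunitiesParams(kappa=1.0, lam=lam0, theta_exp=1.0)
        return InterveningOpportunitiesParams(kappa=scale_for(unit), lam=lam0, theta_exp=1.0)
    raise ConfigurationError(f"unknown model id {model_id!r}")


def _profiled_params(model_id, params, observed, locs, geom, mask):
    """Replace the multiplicative scale(s) of ``params`` with their
    closed-form Poisson-ML values.

    Every model factorises as ``scale * f(shape)``; for fixed shape the
    likelihood is maximised at ``scale = sum(y) / sum(f)`` over the cells
    where ``f > 0``.  Profiling the scale analytically removes the long
    scale-shape ridge from the numerical optimisation.  The gravity model
    with a distance cut-off has one scale per branch, profiled separately
    over the cells each branch covers.
    """
    use = ~np.eye(locs.n, dtype=bool)
    if mask is not None:
        use = use & np.asarray(mask, bool)
    y = observed.values

    def opt_scale(f, cells):
        support = cells & (f > 0)
        F = f[support].sum()
        Y = y[support].sum()
        if F <= 0 or Y <= 0:
            return PREDICTION_FLOOR
        return Y / F

    if model_id == "gravity_distance":
        f_short = predict_matrix("gravity", replace(params.short, theta=1.0), locs, geom).values
        f_long = predict_matrix("gravity", replace(params.long, theta=1.0), locs, geom).values
        is_short = geom.distances <= params.delta
        th1 = opt_scale(f_short, use & is_short)
        th2 = opt_scale(f_long, use & ~is_short)
        return GravityDistanceParams(
            delta=params.delta,
            short=replace(params.short, theta=th1),
            long=replace(params.long, theta=th2),
        )
    scale_field = "kappa" if model_id == "intervening_opportunities" else "theta"
    unit = replace(params, **{scale_field: 1.0})
    f = predict_matrix(model_id, unit, locs, geom).values
    return replace(params, **{scale_field: opt_scale(f, use)})


def fit_model(
    model_id: str,
    observed: ODMatrix,
    locs: LocationSet,
    geom: PairwiseGeometry,
    config: Optional[FitConfig] = None,
    train_mask: Optional[np.ndarray] = None,
) -> FitResult:
    """Maximum-likelihood fit of one base model.

    Deterministic given ``config.seed``: the first start is data-driven and
    restarts perturb it with seeded Gaussian jitter.  The scale parameters
    are concentrated out of the likelihood analytically (see
    :func:`_profiled_params`); BFGS handles the remaining shape parameters.
    A fit that never satisfies the gradient tolerance is returned with
    ``converged=False`` and a warning — never a silent success.
    """
    cfg = config or FitConfig()
    if model_id not in MODEL_IDS:
        raise ConfigurationError(f"unknown model id {model_id!r}")
    if not isinstance(observed, ODMatrix):
        raise InvalidInputError("observed must be an ODMatrix")

    def profiled(x):
        params = _unpack(model_id, x, cfg)
        params = _profiled_params(model_id, params, observed, locs, geom, train_mask)
        pred = predict_matrix(model_id, params, locs, geom)
        return poisson_nll(observed, pred, mask=train_mask), params

    def objective(x):
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            try:
                val, _ = profiled(x)
            except (ValueError, FloatingPointError):
                return _BIG
        return val if np.isfinite(val) else _BIG

    x0 = _pack(model_id, _start_params(model_id, observed, locs, geom, cfg, train_mask), cfg)
    rng = np.random.default_rng(cfg.seed)
    best = None
    n_tries = 1 + max(0, cfg.max_restarts)
    for attempt in range(n_tries):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.25, size=x0.shape)
        res = minimize(
            objective,
            start,
            method="BFGS",
            jac="3-point",
            options={"gtol": cfg.tolerance, "maxiter": cfg.max_iterations},
        )
        # BFGS may stop on line-search precision loss at a numerically flat
        # optimum; accept if the gradient is small relative to the NLL scale.
        grad_ok = np.max(np.abs(res.jac)) <= 1e-6 * (1.0 + abs(res.fun))
        converged = bool(res.success or grad_ok)
        if best is None or res.fun < best[0].fun:
            best = (res, converged)
        if converged:
            best = min([best, (res, converged)], key=lambda t: t[0].fun)
            break
    res, converged = best
    if not converged:
        logger.warning(
            "fit of %s did not converge after %d start(s); returning best NLL %.6g",
            model_id, n_tries, res.fun,
        )
    nll, params = profiled(res.x)
    return FitResult(
        model_id=model_id,
        params=params,
        neg_log_likelihood=float(nll),
        converged=converged,
        n_iterations=int(res.nit),
        seed=cfg.seed,
    )
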