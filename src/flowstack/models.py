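"""The five base movement models.

Each model maps origin population ``m``, destination population ``n``,
separation ``r`` (km) and/or intervening population ``s`` to an expected
flow ``T_ij``:

* **gravity** — ``T = θ m^α n^β / r^γ``.
* **gravity_distance** — gravity with separate parameter sets for trips
  shorter and longer than a cut-off distance δ (the boundary ``r = δ``
  uses the short-range set).
* **radiation** — ``T = θ m n / ((m+s)(m+n+s))``: commuters take the
  closest acceptable job, with opportunities proportional to population.
* **radiation_selection** — ``T = θ (1−λ^P/P)(1−λ^Q/Q)/(1−λ^R/R)`` with
  ``P = m``, ``Q = n``, ``R = m+n+s`` and per-opportunity selection
  probability λ ∈ (0,1); ``λ^P`` underflows cleanly to zero for
  city-sized populations.
* **intervening_opportunities** — Schneider's stochastic form
  ``T = κ (e^{−λ(s+m)^θ} − e^{−λ(s+m+n)^θ})``; ``e^{−λ}`` is the
  probability that a single opportunity is not attractive enough, and κ
  is an explicit proportionality constant so the model has the absolute
  intensity scale Poisson fitting requires.

Flux functions are defined per cell (the testable unit) and accept
scalars or aligned arrays; :func:`predict_matrix` vectorises them over
all ordered region pairs.  Self-loops are not modelled: every predicted
matrix has an exactly-zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedFluxError,
)
from .spatial import LocationSet, PairwiseGeometry

#: Stable model identifiers used in configs, CLI flags and serialised output.
MODEL_IDS = (
    "gravity",
    "gravity_distance",
    "radiation",
    "radiation_selection",
    "intervening_opportunities",
)

#: Floor applied to predictions before any logarithm (shared with the
#: fitting and ensemble modules).
PREDICTION_FLOOR = 1e-10


@dataclass(frozen=True)
class ODMatrix:
    """Square origin-destination matrix of non-negative flows with a zero
    diagonal, aligned to a :class:`~flowstack.spatial.LocationSet`."""

    values: np.ndarray
    ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        ids = tuple(str(i) for i in self.ids)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("OD matrix must be square")
        if v.shape[0] != len(ids):
            raise InvalidInputError("OD matrix size must match number of region ids")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("OD matrix entries must be finite")
        if np.any(v < 0):
            raise InvalidInputError("OD matrix entries must be non-negative")
        if np.any(np.diag(v) != 0):
            raise InvalidInputError("OD matrix diagonal (self-loops) must be zero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n, dtype=bool)


@dataclass(frozen=True)
class GravityParams:
    theta: float  # overall scale, > 0
    alpha: float  # origin-population exponent
    beta: float   # destination-population exponent
    gamma: float  # distance-decay exponent

    def __post_init__(self):
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise InvalidParameterError("gravity theta must be positive")


@dataclass(frozen=True)
class GravityDistanceParams:
    delta: float           # cut-off distance, km, > 0
    short: GravityParams   # applied where r <= delta
    long: GravityParams    # applied where r > delta

    def __post_init__(self):
        if not (np.isfinite(self.delta) and self.delta > 0):
            raise InvalidParameterError("distance cut-off delta must be positive")


@dataclass(frozen=True)
class RadiationParams:
    # Interpreted as the commuting proportion when fitting counts, but fitted
    # as a free positive scale so normalised intensity data remain in range.
    theta: float

    def __post_init__(self):
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise InvalidParameterError("radiation theta must be positive")


@dataclass(frozen=True)
class RadiationSelectionParams:
    theta: float  # scale, > 0
    lam: float    # per-opportunity selection parameter, in (0, 1)

    def __post_init__(self):
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise InvalidParameterError("radiation-selection theta must be positive")
        if not (0.0 < self.lam < 1.0):
            raise InvalidParameterError("selection lambda must lie strictly in (0, 1)")


@dataclass(frozen=True)
class InterveningOpportunitiesParams:
    kappa: float      # proportionality constant, > 0
    lam: float        # opportunity-rejection rate, > 0 (e^{-lam} = miss prob.)
    theta_exp: float  # exponent on the opportunity count, > 0

    def __post_init__(self):
        for name in ("kappa", "lam", "theta_exp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"intervening-opportunities {name} must be positive")


def gravity_flux(params: GravityParams, m, n, r):
    """``θ m^α n^β / r^γ`` for one (or many) origin-destination pairs."""
    m, n, r = np.asarray(m, float), np.asarray(n, float), np.asarray(r, float)
    if params.gamma > 0 and np.any(r == 0):
        raise UndefinedFluxError(
            "gravity flux undefined at zero distance with positive distance exponent; "
            "self-loops must be routed to the zero-diagonal rule"
        )
    with np.errstate(divide="ignore"):
        return params.theta * m ** params.alpha * n ** params.beta / r ** params.gamma


def gravity_distance_flux(params: GravityDistanceParams, m, n, r):
    """Gravity flux with the short-range set where ``r <= δ``, long-range
    set where ``r > δ``."""
    m, n, r = np.asarray(m, float), np.asarray(n, float), np.asarray(r, float)
    short = gravity_flux(params.short, m, n, r)
    long_ = gravity_flux(params.long, m, n, r)
    return np.where(r <= params.delta, short, long_)


def radiation_flux(params: RadiationParams, m, n, s):
    """``θ m n / ((m+s)(m+n+s))``."""
    m, n, s = np.asarray(m, float), np.asarray(n, float), np.asarray(s, float)
    return params.theta * m * n / ((m + s) * (m + n + s))


def _one_minus_pow_over(lam: float, x):
    # (1 - lam**x / x) with lam**x computed as exp(x log lam); for large x the
    # power underflows to exactly 0 and the factor becomes 1.
    x = np.asarray(x, float)
    with np.errstate(under="ignore"):
        p = np.exp(x * np.log(lam))
    return 1.0 - p / x


def radiation_selection_flux(params: RadiationSelectionParams, P, Q, R):
    """``θ (1−λ^P/P)(1−λ^Q/Q) / (1−λ^R/R)`` with ``R = m + n + s``."""
    if not (0.0 < params.lam < 1.0):
        raise InvalidParameterError("selection lambda must lie strictly in (0, 1)")
    num = _one_minus_pow_over(params.lam, P) * _one_minus_pow_over(params.lam, Q)
    return params.theta * num / _one_minus_pow_over(params.lam, R)


def intervening_opportunities_flux(params: InterveningOpportunitiesParams, m, n, s):
    """``κ (e^{−λ(s+m)^θ} − e^{−λ(s+m+n)^θ})``."""
    m, n, s = np.asarray(m, float), np.asarray(n, float), np.asarray(s, float)
    with np.errstate(under="ignore"):
        near = np.exp(-params.lam * (s + m) ** params.theta_exp)
        far = np.exp(-params.lam * (s + m + n) ** params.theta_exp)
    return params.kappa * (near - far)


_FLUX_BY_MODEL = {
    "gravity": ("mnr", gravity_flux),
    "gravity_distance": ("mnr", gravity_distance_flux),
    "radiation": ("mns", radiation_flux),
    "radiation_selection": ("PQR", radiation_selection_flux),
    "intervening_opportunities": ("mns", intervening_opportunities_flux),
}


def predict_matrix(model_id: str, params, locs: LocationSet, geom: PairwiseGeometry) -> ODMatrix:
    """Predicted OD matrix for one model: every off-diagonal cell holds the
    model's flux, the diagonal is exactly zero."""
    if model_id not in _FLUX_BY_MODEL:
        raise ConfigurationError(
            f"unknown model id {model_id!r}; expected one of {MODEL_IDS}"
        )
    if geom.n != locs.n:
        raise InvalidInputError("geometry does not match the location set")
    z = locs.n
    out = np.zeros((z, z))
    if z > 1:
        off = ~np.eye(z, dtype=bool)
        m = np.broadcast_to(locs.populations[:, None], (z, z))[off]
        n = np.broadcast_to(locs.populations[None, :], (z, z))[off]
        r = geom.distances[off]
        s = geom.intervening[off]
        signature, flux = _FLUX_BY_MODEL[model_id]
        if signature == "mnr":
            vals = flux(params, m, n, r)
        elif signature == "mns":
            vals = flux(params, m, n, s)
        else:  # radiation with selection: P = m_i, Q = n_j, R = m_i + n_j + s_ij
            vals = flux(params, m, n, m + n + s)
        out[off] = vals
    return ODMatrix(values=out, ids=locs.ids)


# ---------------------------------------------------------------------------
# Parameter (de)serialisation: {"model": <id>, "params": {<name>: <value>}}
# ---------------------------------------------------------------------------

def params_to_dict(model_id: str, params) -> dict:
    """Flatten a parameter object into plain name→value pairs."""
    if model_id == "gravity_distance":
        d = {"delta": params.delta}
        for tag, p in (("short", params.short), ("long", params.long)):
            for k, v in asdict(p).items():
                d[f"{k}_{tag}"] = v
        return d
    return asdict(params)


def params_from_dict(model_id: str, d: dict):
    """Inverse of :func:`params_to_dict`."""
    if model_id == "gravity":
        return GravityParams(**d)
    if model_id == "gravity_distance":
        short = GravityParams(**{k: d[f"{k}_short"] for k in ("theta", "alpha", "beta", "gamma")})
        long_ = GravityParams(**{k: d[f"{k}_long"] for k in ("theta", "alpha", "beta", "gamma")})
        return GravityDistanceParams(delta=d["delta"], short=short, long=long_)
    if model_id == "radiation":
        return RadiationParams(**d)
    if model_id == "radiation_selection":
        return RadiationSelectionParams(**d)
    if model_id == "intervening_opportunities":
        return InterveningOpportunitiesParams(**d)
    raise ConfigurationError(f"unknown model id {model_id!r}")
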