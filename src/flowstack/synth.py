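"""Seeded synthetic location sets and OD flow matrices.

The generator emulates the statistical structure of regional commuting
data: heterogeneous region populations (log-uniform between 3,000 and
25,000, the size band of Australian SA2 statistical regions), point
population centres scattered over a study window either uniformly or
clustered around urban hubs, and distance-decaying flow counts with
independent Poisson noise and no self-loops.  Two sampling regimes are
supported: ``census_like`` integer trip counts and ``gps_like``
matrix-normalised intensities (the whole matrix sums to one, as for
aggregated app-derived trip frequencies).

Flows are generated from one base model or from a convex mixture of
models — mixtures are first-class because a stacked ensemble only has
something to gain when no single base model is the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ScenarioError
from .models import (
    MODEL_IDS,
    GravityParams,
    InterveningOpportunitiesParams,
    ODMatrix,
    predict_matrix,
)
from .spatial import LocationSet, PairwiseGeometry

#: Default generating parameters.  Gravity: mild population exponents and a
#: distance decay of 1.5 give a realistic mix of heavy short-range and thin
#: long-range flows; theta is scaled so typical cell counts are in the tens
#: for SA2-sized populations on a 500 km window.  Intervening opportunities:
#: a square-root opportunity exponent with a rejection rate that halves the
#: retention probability every few ten-thousand opportunities, kappa scaled
#: to comparable counts.
DEFAULT_GRAVITY_PARAMS = GravityParams(theta=0.3, alpha=0.8, beta=0.6, gamma=1.5)
DEFAULT_IO_PARAMS = InterveningOpportunitiesParams(kappa=300.0, lam=0.02, theta_exp=0.5)

POPULATION_RANGE = (3000.0, 25000.0)  # SA2-like region sizes

_MAX_MEAN = 1e12


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of one synthetic dataset.

    components
        Sequence of ``(model_id, params)`` pairs; ``weights`` (default
        equal) combine their expectation matrices convexly.
    noise
        ``"expectation"`` returns the mean matrix itself; ``"poisson"``
        samples each off-diagonal cell independently.
    regime
        ``"census_like"`` rounds to integer counts; ``"gps_like"``
        normalises the matrix to sum to one.
    """

    n_regions: int
    components: Tuple[tuple, ...] = (("gravity", DEFAULT_GRAVITY_PARAMS),)
    weights: Optional[Tuple[float, ...]] = None
    seed: int = 0
    pop_min: float = POPULATION_RANGE[0]
    pop_max: float = POPULATION_RANGE[1]
    spatial_law: str = "uniform_square"  # or "clustered"
    side_km: float = 500.0
    n_hubs: int = 3
    hub_sigma_km: float = 25.0
    noise: str = "poisson"               # or "expectation"
    regime: str = "census_like"          # or "gps_like"

    def __post_init__(self):
        if self.n_regions < 2:
            raise ScenarioError("a scenario needs at least 2 regions")
        if not (0 < self.pop_min <= self.pop_max):
            raise ScenarioError("population bounds must satisfy 0 < pop_min <= pop_max")
        if self.spatial_law not in ("uniform_square", "clustered"):
            raise ScenarioError(f"unknown spatial law {self.spatial_law!r}")
        if self.noise not in ("expectation", "poisson"):
            raise ScenarioError(f"unknown noise mode {self.noise!r}")
        if self.regime not in ("census_like", "gps_like"):
            raise ScenarioError(f"unknown regime {self.regime!r}")
        comps = tuple((mid, p) for mid, p in self.components)
        for mid, _ in comps:
            if mid not in MODEL_IDS:
                raise ScenarioError(f"unknown generating model {mid!r}")
        w = self.weights
        if w is None:
            w = tuple(1.0 / len(comps) for _ in comps)
        else:
            w = tuple(float(v) for v in w)
            if len(w) != len(comps) or any(v < 0 for v in w) or sum(w) <= 0:
                raise ScenarioError("weights must be non-negative and match the components")
            w = tuple(v / sum(w) for v in w)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", w)


def gravity_io_mixture_scenario(n_regions: int = 60, seed: int = 0, **kwargs) -> SyntheticScenario:
    """The study's reference mixture: a 50/50 gravity + intervening-
    opportunities blend with Poisson noise, census-like counts."""
    return SyntheticScenario(
        n_regions=n_regions,
        components=(
            ("gravity", DEFAULT_GRAVITY_PARAMS),
            ("intervening_opportunities", DEFAULT_IO_PARAMS),
        ),
        weights=(0.5, 0.5),
        seed=seed,
        **kwargs,
    )


def generate_locations(scenario: SyntheticScenario) -> LocationSet:
    """Seeded region set: log-uniform populations in [pop_min, pop_max];
    coordinates uniform on the study square or Gaussian around hubs
    (regions assigned to hubs round-robin, so every hub is populated)."""
    rng = np.random.default_rng([scenario.seed, 0])
    n = scenario.n_regions
    pops = np.exp(rng.uniform(np.log(scenario.pop_min), np.log(scenario.pop_max), size=n))
    if scenario.spatial_law == "uniform_square":
        coords = rng.uniform(0.0, scenario.side_km, size=(n, 2))
    else:
        hubs = rng.uniform(0.0, scenario.side_km, size=(scenario.n_hubs, 2))
        assign = np.arange(n) % scenario.n_hubs
        coords = hubs[assign] + rng.normal(0.0, scenario.hub_sigma_km, size=(n, 2))
    ids = tuple(f"r{i:03d}" for i in range(n))
    return LocationSet(ids=ids, coords=coords, populations=pops, coord_mode="projected_km")


def expectation_matrix(scenario: SyntheticScenario, locs: LocationSet, geom: PairwiseGeometry) -> np.ndarray:
    """Convex combination of the component models' predicted matrices."""
    mean = np.zeros((locs.n, locs.n))
    for w, (mid, params) in zip(scenario.weights, scenario.components):
        mean += w * predict_matrix(mid, params, locs, geom).values
    if not np.all(np.isfinite(mean)) or mean.max() > _MAX_MEAN:
        raise ScenarioError(
            "expected flows overflow; use a smaller scale parameter (theta/kappa) "
            "in the generating model"
        )
    return mean


def generate_flows(scenario: SyntheticScenario, locs: LocationSet, geom: PairwiseGeometry) -> ODMatrix:
    """Observed OD matrix under the scenario's noise model and regime."""
    mean = expectation_matrix(scenario, locs, geom)
    off = ~np.eye(locs.n, dtype=bool)
    values = mean.copy()
    if scenario.noise == "poisson":
        rng = np.random.default_rng([scenario.seed, 1])
        values[off] = rng.poisson(mean[off]).astype(float)
    if scenario.regime == "census_like":
        # Counts are integers; expectation mode passes the exact means
        # through (a noise-free diagnostic, used for recovery checks).
        if scenario.noise == "poisson":
            values = np.rint(values)
    else:  # gps_like: normalised intensity of contact
        total = values[off].sum()
        if total <= 0:
            raise ScenarioError("cannot normalise an all-zero flow matrix")
        values = values / total
    np.fill_diagonal(values, 0.0)
    return ODMatrix(values=values, ids=locs.ids)


def generate(scenario: SyntheticScenario):
    """Convenience: ``(locations, geometry, observed OD matrix)``."""
    locs = generate_locations(scenario)
    geom = PairwiseGeometry.from_locations(locs)
    return locs, geom, generate_flows(scenario, locs, geom)


def scenario_from_dict(d: dict) -> SyntheticScenario:
    """Build a scenario from a plain config mapping.

    ``components`` is a list of ``{model: <id>, params: {<name>: <value>},
    weight: <w>}`` entries; omitted params fall back to the defaults for
    gravity and intervening opportunities."""
    from .models import params_from_dict

    d = dict(d)
    comps_raw = d.pop("components", None)
    if comps_raw is None:
        comps, weights = None, None
    else:
        comps, weights = [], []
        defaults = {
            "gravity": DEFAULT_GRAVITY_PARAMS,
            "intervening_opportunities": DEFAULT_IO_PARAMS,
        }
        for entry in comps_raw:
            mid = entry["model"]
            if "params" in entry:
                params = params_from_dict(mid, entry["params"])
            elif mid in defaults:
                params = defaults[mid]
            else:
                raise ScenarioError(f"component {mid!r} needs explicit params")
            comps.append((mid, params))
            weights.append(float(entry.get("weight", 1.0)))
    kwargs = dict(d)
    if comps is not None:
        kwargs["components"] = tuple(comps)
        kwargs["weights"] = tuple(weights)
    return SyntheticScenario(**kwargs)
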