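"""Regions, pairwise distances and intervening populations.

A :class:`LocationSet` holds point population centres: each region has an
identifier, a coordinate pair and a population size.  From it we derive the
two geometric quantities every movement model consumes:

* the distance matrix ``r_ij`` (kilometres), Euclidean on projected
  coordinates or great-circle on longitude/latitude;
* the intervening-population matrix ``s_ij``: the total population living
  strictly closer to the origin *i* than the destination *j* is, excluding
  both endpoints.  This is the quantity the radiation and intervening-
  opportunities models are built on.

The intervening population uses a circle centred at the ORIGIN with radius
``r_ij``; regions lying exactly on the circle are excluded (strict
inequality).  Distances are straight-line only — road distances and travel
times are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import InvalidInputError

EARTH_RADIUS_KM = 6371.0

#: Coordinate interpretation flags for :class:`LocationSet`.
PROJECTED_KM = "projected_km"
LONLAT_DEGREES = "lonlat_degrees"
COORD_MODES = (PROJECTED_KM, LONLAT_DEGREES)


@dataclass(frozen=True)
class LocationSet:
    """An ordered set of regions with coordinates and population sizes.

    Parameters
    ----------
    ids
        Unique region identifiers, order-defining for every matrix built
        from this set.
    coords
        ``(n, 2)`` array.  In ``projected_km`` mode columns are x/y in
        kilometres; in ``lonlat_degrees`` mode they are longitude and
        latitude in degrees.
    populations
        Strictly positive region population sizes (persons).
    coord_mode
        One of ``"projected_km"`` or ``"lonlat_degrees"``.
    """

    ids: tuple
    coords: np.ndarray
    populations: np.ndarray
    coord_mode: str = PROJECTED_KM

    def __post_init__(self):
        ids = tuple(str(i) for i in self.ids)
        coords = np.asarray(self.coords, dtype=float)
        pops = np.asarray(self.populations, dtype=float)
        if len(set(ids)) != len(ids):
            raise InvalidInputError("region ids must be unique")
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise InvalidInputError("coords must be an (n, 2) array")
        if not (len(ids) == coords.shape[0] == pops.shape[0]):
            raise InvalidInputError("ids, coords and populations must have equal length")
        if not np.all(np.isfinite(coords)):
            raise InvalidInputError("coordinates must be finite")
        if not np.all(np.isfinite(pops) & (pops > 0)):
            raise InvalidInputError("populations must be finite and strictly positive")
        if self.coord_mode not in COORD_MODES:
            raise InvalidInputError(
                f"coord_mode must be one of {COORD_MODES}, got {self.coord_mode!r}"
            )
        if self.coord_mode == LONLAT_DEGREES:
            lon, lat = coords[:, 0], coords[:, 1]
            if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
                raise InvalidInputError(
                    "lonlat coordinates must satisfy |lon| <= 180 and |lat| <= 90"
                )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "populations", pops)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def total_population(self) -> float:
        return float(self.populations.sum())


def pairwise_distances(locs: LocationSet) -> np.ndarray:
    """Symmetric, zero-diagonal distance matrix in kilometres.

    Euclidean in ``projected_km`` mode; great-circle (haversine, Earth
    radius 6371 km) in ``lonlat_degrees`` mode.
    """
    if locs.n == 1:
        return np.zeros((1, 1))
    if locs.coord_mode == PROJECTED_KM:
        d = squareform(pdist(locs.coords))
    else:
        lon = np.radians(locs.coords[:, 0])
        lat = np.radians(locs.coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (
            np.sin(dlat / 2.0) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
        )
        d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def intervening_population(locs: LocationSet, distances: np.ndarray) -> np.ndarray:
    """Matrix ``s_ij``: total population strictly inside the circle centred
    at origin *i* with radius ``r_ij``, excluding regions *i* and *j*.

    The destination *j* sits exactly on the circle, so the strict inequality
    excludes it automatically; the origin's own population is subtracted
    whenever ``r_ij > 0``.  Diagonal entries are zero.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape != (locs.n, locs.n):
        raise InvalidInputError(
            f"distance matrix shape {d.shape} does not match {locs.n} regions"
        )
    pops = locs.populations
    s = np.empty_like(d)
    for i in range(locs.n):
        di = d[i]
        # closer[j, k] == True iff region k is strictly closer to i than j is
        closer = di[None, :] < di[:, None]
        s[i] = closer @ pops - np.where(di > 0, pops[i], 0.0)
    np.fill_diagonal(s, 0.0)
    return np.maximum(s, 0.0)


@dataclass(frozen=True)
class PairwiseGeometry:
    """Distance matrix ``r_ij`` (km) and intervening-population matrix
    ``s_ij`` (persons) for one :class:`LocationSet`."""

    distances: np.ndarray
    intervening: np.ndarray
    n: int = field(default=0)

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        s = np.asarray(self.intervening, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape != s.shape:
            raise InvalidInputError("distances and intervening must be equal square matrices")
        if not np.allclose(d, d.T):
            raise InvalidInputError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0) or np.any(np.diag(s) != 0):
            raise InvalidInputError("distance and intervening diagonals must be zero")
        if np.any(d < 0) or np.any(s < 0):
            raise InvalidInputError("distances and intervening populations must be non-negative")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "intervening", s)
        object.__setattr__(self, "n", d.shape[0])

    @classmethod
    def from_locations(cls, locs: LocationSet) -> "PairwiseGeometry":
        d = pairwise_distances(locs)
        s = intervening_population(locs, d)
        return cls(distances=d, intervening=s)
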