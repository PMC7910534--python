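"""CSV/JSON dialects, run configuration and the unit-interval scaling.

On-disk formats
---------------
Locations: CSV with header ``id,x,y,population`` (projected kilometres)
or ``id,lon,lat,population`` (degrees); UTF-8, no missing values.

OD flows: long format ``origin,destination,count`` is canonical (large
matrices are sparse; absent pairs are zero); a wide square matrix with
an ``id`` header column is accepted for small tables.  Self-loop rows
with a positive count are ignored with a warning — the models set all
self-loops to zero.

Fitted parameters, ensembles and CV summaries are serialised as JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .fitting import FitConfig, FitResult
from .models import MODEL_IDS, ODMatrix, params_from_dict, params_to_dict
from .spatial import COORD_MODES, LocationSet

logger = logging.getLogger("flowstack")

_LOC_HEADERS = {
    ("id", "x", "y", "population"): "projected_km",
    ("id", "lon", "lat", "population"): "lonlat_degrees",
}


def read_locations(path) -> LocationSet:
    """Read a location table, inferring the coordinate mode from the header."""
    df = pd.read_csv(path, dtype={0: str})
    header = tuple(df.columns)
    if header not in _LOC_HEADERS:
        raise InvalidInputError(
            f"{path}: expected header id,x,y,population or id,lon,lat,population; got {header}"
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based incl. header
        raise InvalidInputError(f"{path}: missing value at row {bad}")
    mode = _LOC_HEADERS[header]
    return LocationSet(
        ids=tuple(df.iloc[:, 0]),
        coords=df.iloc[:, 1:3].to_numpy(float),
        populations=df.iloc[:, 3].to_numpy(float),
        coord_mode=mode,
    )


def write_locations(locs: LocationSet, path) -> None:
    cols = ("x", "y") if locs.coord_mode == "projected_km" else ("lon", "lat")
    df = pd.DataFrame(
        {
            "id": locs.ids,
            cols[0]: locs.coords[:, 0],
            cols[1]: locs.coords[:, 1],
            "population": locs.populations,
        }
    )
    df.to_csv(path, index=False)


def read_od(path, ids) -> ODMatrix:
    """Read an OD matrix in long (``origin,destination,count``) or wide
    (square with ``id`` header) format, validated against ``ids``."""
    ids = tuple(str(i) for i in ids)
    df = pd.read_csv(path)
    header = tuple(df.columns)
    if header == ("origin", "destination", "count"):
        return _od_from_long(path, df, ids)
    if header[0] == "id":
        return _od_from_wide(path, df, ids)
    raise InvalidInputError(
        f"{path}: expected long header origin,destination,count or a wide matrix with an 'id' column"
    )


def _od_from_long(path, df, ids) -> ODMatrix:
    index = {rid: i for i, rid in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for row, (o, d, c) in enumerate(zip(df["origin"].astype(str), df["destination"].astype(str), df["count"]), start=2):
        if o not in index or d not in index:
            raise InvalidInputError(f"{path}: unknown region id at row {row}")
        c = float(c)
        if not np.isfinite(c) or c < 0:
            raise InvalidInputError(f"{path}: negative or non-finite count at row {row}")
        if o == d:
            if c > 0:
                logger.warning("%s: row %d is a self-loop with positive count; ignored", path, row)
            continue
        values[index[o], index[d]] = c
    return ODMatrix(values=values, ids=ids)


def _od_from_wide(path, df, ids) -> ODMatrix:
    if len(df.columns) - 1 != len(df):
        raise InvalidInputError(f"{path}: wide OD matrix must be square")
    row_ids = tuple(df["id"].astype(str))
    col_ids = tuple(df.columns[1:])
    if row_ids != ids or col_ids != ids:
        raise InvalidInputError(f"{path}: wide OD ids must match the location table exactly")
    values = df.iloc[:, 1:].to_numpy(float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        bad = int(np.argwhere(~(np.isfinite(values) & (values >= 0)))[0][0]) + 2
        raise InvalidInputError(f"{path}: negative or non-finite count at row {bad}")
    if np.any(np.diag(values) > 0):
        logger.warning("%s: positive self-loop counts on the diagonal; ignored", path)
    np.fill_diagonal(values, 0.0)
    return ODMatrix(values=values, ids=ids)


def write_od(od: ODMatrix, path, fmt: str = "long") -> None:
    """Write an OD matrix; long format drops zero cells (canonical)."""
    if fmt == "long":
        rows = np.argwhere((od.values > 0) & od.offdiag_mask())
        df = pd.DataFrame(
            {
                "origin": [od.ids[i] for i, _ in rows],
                "destination": [od.ids[j] for _, j in rows],
                "count": [od.values[i, j] for i, j in rows],
            },
            columns=["origin", "destination", "count"],
        )
        df.to_csv(path, index=False)
    elif fmt == "wide":
        df = pd.DataFrame(od.values, columns=od.ids)
        df.insert(0, "id", od.ids)
        df.to_csv(path, index=False)
    else:
        raise InvalidInputError(f"unknown OD format {fmt!r}")


def scale_unit(predicted: ODMatrix) -> ODMatrix:
    """Divide by the maximum entry so all predictions lie in [0, 1]
    (the scaling used to compare prediction maps); the diagonal stays 0."""
    top = predicted.values.max()
    if top <= 0:
        raise InvalidInputError("cannot unit-scale an all-zero matrix")
    return ODMatrix(values=predicted.values / top, ids=predicted.ids)


# ---------------------------------------------------------------------------
# Fit-result / ensemble serialisation
# ---------------------------------------------------------------------------

def fit_result_to_json(result: FitResult, path) -> None:
    payload = {
        "model": result.model_id,
        "params": {k: float(v) for k, v in params_to_dict(result.model_id, result.params).items()},
        "neg_log_likelihood": result.neg_log_likelihood,
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "seed": result.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def fit_result_from_json(path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    return FitResult(
        model_id=payload["model"],
        params=params_from_dict(payload["model"], payload["params"]),
        neg_log_likelihood=payload["neg_log_likelihood"],
        converged=payload["converged"],
        n_iterations=payload["n_iterations"],
        seed=payload["seed"],
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured configuration shared by the CLI subcommands."""

    locations: Optional[str] = None
    flows: Optional[str] = None
    output_dir: str = "."
    models: tuple = MODEL_IDS
    coordinate_mode: str = "projected_km"
    seed: int = 0
    fitting: dict = field(default_factory=dict)    # max_iterations, tolerance, max_restarts, fix_delta
    cv: dict = field(default_factory=dict)         # k, seed
    ensemble: dict = field(default_factory=dict)   # ridge, max_iter, tol
    scenario: dict = field(default_factory=dict)   # synthetic-data description
    logging_level: str = "INFO"

    def __post_init__(self):
        if self.coordinate_mode not in COORD_MODES:
            raise InvalidInputError(f"coordinate_mode must be one of {COORD_MODES}")
        for mid in self.models:
            if mid not in MODEL_IDS:
                raise InvalidInputError(f"unknown model id {mid!r} in config")
        if int(self.cv.get("k", 5)) < 2:
            raise InvalidInputError("cv.k must be at least 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            seed=int(self.fitting.get("seed", self.seed)),
            max_iterations=int(self.fitting.get("max_iterations", 500)),
            tolerance=float(self.fitting.get("tolerance", 1e-6)),
            max_restarts=int(self.fitting.get("max_restarts", 3)),
            fix_delta=self.fitting.get("fix_delta"),
        )

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        blob = json.dumps(
            {f: getattr(self, f) if f != "models" else list(self.models)
             for f in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
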