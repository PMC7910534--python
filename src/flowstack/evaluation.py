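"""Cross-validated evaluation by Poisson deviance.

Hold-out evaluation follows k-fold cross-validation (default k = 5) over
off-diagonal OD *cells*: each fold holds out ~1/k of the observed flows,
the five base models are refitted on the remaining cells only, the
ensemble is stacked on those fold-trained base predictions (no leakage),
and every model — plus the unweighted "mean" average of the five base
predictions — is scored on the held-out cells with the Poisson deviance

    D = 2 sum[ y log(y/mu) - (y - mu) ]        (y = 0 term -> 2 mu).

Deviances are comparable only between models evaluated on the same data;
the report therefore never aggregates across datasets, only across folds
of one dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleConfig, _deviance, fit_ensemble, predict_ensemble
from .errors import InvalidInputError
from .fitting import FitConfig, fit_model
from .models import MODEL_IDS, PREDICTION_FLOOR, ODMatrix, predict_matrix
from .spatial import LocationSet, PairwiseGeometry

logger = logging.getLogger("flowstack")

#: Report rows added on top of the base models.
ENSEMBLE_ID = "ensemble"
MEAN_ID = "mean"


def poisson_deviance(observed, predicted) -> float:
    """Poisson deviance between observed and predicted flow vectors.

    Zero iff the vectors agree elementwise; predictions are floored at
    1e-10, and the ``y = 0`` term takes its limit value ``2 mu``.
    """
    y = np.asarray(observed, float).ravel()
    mu = np.asarray(predicted, float).ravel()
    if y.shape != mu.shape:
        raise InvalidInputError("observed and predicted vectors must have equal length")
    if np.any(y < 0):
        raise InvalidInputError("observed values must be non-negative")
    # the floor protects only the logarithm; the linear term keeps the raw
    # prediction so a perfect fit (including zero cells) scores exactly 0,
    # and the final clamp removes the floating-point cancellation residue
    from scipy.special import xlogy
    dev = 2.0 * np.sum(xlogy(y, y / np.maximum(mu, PREDICTION_FLOOR)) - (y - mu))
    return float(max(dev, 0.0))


@dataclass(frozen=True)
class FoldAssignment:
    """Seeded partition of the off-diagonal cells into k folds of
    near-equal size (sizes differ by at most one)."""

    k: int
    seed: int
    cells: np.ndarray    # (n_cells, 2) off-diagonal (i, j) indices
    fold_of: np.ndarray  # fold index in 0..k-1 per cell

    def test_mask(self, fold: int, n: int) -> np.ndarray:
        """Boolean matrix marking the held-out cells of one fold."""
        mask = np.zeros((n, n), dtype=bool)
        sel = self.fold_of == fold
        mask[self.cells[sel, 0], self.cells[sel, 1]] = True
        return mask


def make_folds(n_regions: int, k: int, seed: int) -> FoldAssignment:
    """Uniform seeded k-fold partition of the off-diagonal OD cells."""
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    n_cells = n_regions * (n_regions - 1)
    if k > n_cells:
        raise InvalidInputError(f"k={k} exceeds the {n_cells} off-diagonal cells")
    cells = np.argwhere(~np.eye(n_regions, dtype=bool))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    fold_of = np.empty(n_cells, dtype=int)
    fold_of[order] = np.arange(n_cells) % k
    return FoldAssignment(k=k, seed=seed, cells=cells, fold_of=fold_of)


@dataclass(frozen=True)
class CVReport:
    """Per-fold held-out deviances for each model on one dataset."""

    deviances: dict      # model id -> np.ndarray of k fold deviances
    k: int
    seed: int
    degraded: tuple      # (fold, model_id) pairs where a base fit failed

    def mean_deviance(self, model_id: str) -> float:
        return float(np.mean(self.deviances[model_id]))

    def spread(self, model_id: str) -> tuple:
        d = self.deviances[model_id]
        return float(np.min(d)), float(np.max(d))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``model,fold,deviance`` (folds numbered 1..k)."""
        rows = [
            {"model": m, "fold": f + 1, "deviance": float(d[f])}
            for m, d in self.deviances.items()
            for f in range(self.k)
        ]
        return pd.DataFrame(rows, columns=["model", "fold", "deviance"])

    def summary(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "degraded": [list(t) for t in self.degraded],
            "models": {
                m: {
                    "mean_deviance": self.mean_deviance(m),
                    "min_deviance": self.spread(m)[0],
                    "max_deviance": self.spread(m)[1],
                    "fold_deviances": [float(v) for v in self.deviances[m]],
                }
                for m in self.deviances
            },
        }


def cross_validate(
    observed: ODMatrix,
    locs: LocationSet,
    geom: PairwiseGeometry,
    model_ids: Sequence[str] = MODEL_IDS,
    k: int = 5,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
    ensemble_config: Optional[EnsembleConfig] = None,
) -> CVReport:
    """k-fold cross-validation of the base models, the stacked ensemble and
    the equal-weight mean baseline.

    Per fold, the base models are fitted with the held-out cells masked out
    of the likelihood; the ensemble is stacked on those same training cells
    using the fold-fitted base predictions; all models are scored on the
    held-out cells only.  The ensemble and mean rows are produced whenever
    all five base models are requested.  A non-convergent base fit marks
    the fold as degraded but the run continues.
    """
    for mid in model_ids:
        if mid not in MODEL_IDS:
            raise InvalidInputError(f"unknown model id {mid!r}")
    fit_cfg = fit_config or FitConfig()
    folds = make_folds(locs.n, k, seed)
    off = observed.offdiag_mask()
    full_stack = tuple(model_ids) == MODEL_IDS

    dev = {m: np.zeros(k) for m in model_ids}
    if full_stack:
        dev[ENSEMBLE_ID] = np.zeros(k)
    dev[MEAN_ID] = np.zeros(k)
    degraded = []

    for f in range(k):
        test_mask = folds.test_mask(f, locs.n)
        train_mask = off & ~test_mask
        y_test = observed.values[test_mask]
        preds = {}
        for mid in model_ids:
            fr = fit_model(
                mid, observed, locs, geom,
                config=replace(fit_cfg, seed=fit_cfg.seed + f),
                train_mask=train_mask,
            )
            if not fr.converged:
                degraded.append((f, mid))
                logger.warning("fold %d: %s did not converge; fold marked degraded", f + 1, mid)
            preds[mid] = predict_matrix(mid, fr.params, locs, geom)
            dev[mid][f] = poisson_deviance(y_test, preds[mid].values[test_mask])
        mean_pred = np.mean([preds[mid].values for mid in model_ids], axis=0)
        dev[MEAN_ID][f] = poisson_deviance(y_test, mean_pred[test_mask])
        if full_stack:
            pred_list = [preds[mid] for mid in MODEL_IDS]
            ens = fit_ensemble(observed, pred_list, config=ensemble_config, train_mask=train_mask)
            mu = predict_ensemble(ens, pred_list)
            dev[ENSEMBLE_ID][f] = poisson_deviance(y_test, mu.values[test_mask])

    return CVReport(deviances=dev, k=k, seed=seed, degraded=tuple(degraded))


def plot_deviance(report: CVReport, path) -> None:
    """Bar chart of mean held-out deviance per model with min/max error
    bars across folds, on a log-scaled y axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = list(report.deviances)
    means = [report.mean_deviance(m) for m in models]
    lo = [means[i] - report.spread(m)[0] for i, m in enumerate(models)]
    hi = [report.spread(m)[1] - means[i] for i, m in enumerate(models)]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(models, means, yerr=[lo, hi], capsize=4, color="#4878a8")
    ax.set_yscale("log")
    ax.set_ylabel("mean held-out Poisson deviance")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
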