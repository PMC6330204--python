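"""Random-Forest upscaling of plot canopy structure to landscape maps.

Candidate predictor layers (band means, GLCM textures, vegetation
indices, focal NDVI statistics) are first screened for inter-correlation
(|r| > 0.6 removes the lower-priority member of the pair), then a
2,000-tree bootstrap-aggregated regression forest links the retained
predictors to plot-measured LAI or FCover.  Model skill is the
out-of-bag variance explained (1 - OOB MSE / response variance);
predictor importance is the permutation increase in OOB mean squared
error, averaged over trees with its standard error.  The fitted forest
predicts LAI/FCover per pixel, and the selected plot-level linear models
chain those canopy maps into ground surface temperature and ground NDVI
maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .habitatstats import ModelFit
from .satfeatures import RasterStack

__all__ = [
    "RFModel",
    "screen_predictors",
    "fit_rf",
    "predict_canopy_map",
    "map_microclimate",
    "DEFAULT_PRIORITY",
]

#: greedy-screening priority: the predictors retained in the final
#: canopy models first, remaining candidates alphabetically after them
DEFAULT_PRIORITY = ["SWIRM", "NIRM", "NIRD", "SWIRD", "NDVIMFocal", "NDVISD"]

CORRELATION_THRESHOLD = 0.6
N_TREES = 2000


def _priority_sort(names, priority):
    order = {n: i for i, n in enumerate(priority)}
    return sorted(names, key=lambda n: (order.get(n, len(priority)), n))


def screen_predictors(table: pd.DataFrame, predictors=None,
                      threshold: float = CORRELATION_THRESHOLD,
                      priority=None) -> list:
    """Drop inter-correlated predictors, keeping the higher-priority one.

    Predictors are visited in priority order; a candidate is retained
    only if its absolute Pearson correlation with every already-retained
    predictor stays at or below the threshold.  Constant columns cannot
    be correlated and are removed with a warning.
    """
    if predictors is None:
        predictors = [c for c in table.columns]
    if len(predictors) < 2:
        raise ValueError("need at least 2 candidate predictors")
    priority = priority or DEFAULT_PRIORITY
    usable = []
    for name in predictors:
        col = table[name].to_numpy(dtype=float)
        if np.nanstd(col) == 0:
            warnings.warn(f"predictor {name!r} is constant; removed",
                          stacklevel=2)
            continue
        usable.append(name)
    retained = []
    for name in _priority_sort(usable, priority):
        x = table[name].to_numpy(dtype=float)
        ok = True
        for kept in retained:
            r = np.corrcoef(x, table[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


@dataclass
class RFModel:
    """A fitted canopy-structure forest with OOB diagnostics."""

    response: str
    predictors: list
    n_trees: int
    oob_variance_explained: float
    importances: pd.DataFrame    # index predictor; columns importance, se
    seed: int
    training_range: tuple
    _forest: RandomForestRegressor = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Random Forest: {self.response} ~ {' + '.join(self.predictors)}",
            f"  trees: {self.n_trees}   OOB variance explained: "
            f"{100 * self.oob_variance_explained:.1f}%",
            "  importance (permutation increase in OOB MSE, with SE):",
        ]
        for name, row in self.importances.iterrows():
            lines.append(f"    {name:<12} {row['importance']:.4f} "
                         f"({row['se']:.4f})")
        return "\n".join(lines)


def _oob_permutation_importance(forest, X, y, rng):
    """Per-tree out-of-bag permutation importance.

    For each tree: the increase in MSE on its out-of-bag samples when one
    predictor's values are permuted.  Returns (mean, se) across trees per
    predictor — the raw mean-decrease-in-accuracy statistic.
    """
    n_samples, n_feat = X.shape
    all_idx = np.arange(n_samples)
    deltas = np.full((len(forest.estimators_), n_feat), np.nan)
    for t, (tree, in_bag) in enumerate(
            zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(all_idx, in_bag, assume_unique=False)
        if len(oob) < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        for j in range(n_feat):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            deltas[t, j] = np.mean((tree.predict(Xp) - yo) ** 2) - base
    mean = np.nanmean(deltas, axis=0)
    n_eff = np.sum(np.isfinite(deltas), axis=0)
    se = np.nanstd(deltas, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return mean, se


def fit_rf(table: pd.DataFrame, response: str, predictors=None,
           n_trees: int = N_TREES, seed: int = 0,
           min_rows: int = 20) -> RFModel:
    """Fit the canopy-structure Random Forest.

    Bootstrap-aggregated regression trees with per-split candidate count
    ceil(p / 3) and minimum leaf size 5; importance computed on the
    out-of-bag samples of each tree.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    if len(predictors) < 1:
        raise ValueError("need at least one predictor")
    data = table[[response, *predictors]].dropna()
    if len(data) < min_rows:
        raise ValueError(
            f"need at least {min_rows} complete rows, have {len(data)}"
        )
    X = data[predictors].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    p = len(predictors)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, int(np.ceil(p / 3))),
        min_samples_leaf=5,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-OOB-sample warnings at small n
        forest.fit(X, y)
    rng = np.random.default_rng(seed)
    imp_mean, imp_se = _oob_permutation_importance(forest, X, y, rng)
    importances = (
        pd.DataFrame({"importance": imp_mean, "se": imp_se},
                     index=pd.Index(predictors, name="predictor"))
        .sort_values("importance", ascending=False)
    )
    return RFModel(
        response=response,
        predictors=list(predictors),
        n_trees=n_trees,
        oob_variance_explained=float(forest.oob_score_),
        importances=importances,
        seed=seed,
        training_range=(float(y.min()), float(y.max())),
        _forest=forest,
    )


def predict_canopy_map(model: RFModel, stack: RasterStack) -> np.ndarray:
    """Per-pixel ensemble-mean canopy prediction.

    A pixel is undefined wherever any trained predictor layer is; a
    missing layer raises, naming it.
    """
    for name in model.predictors:
        if name not in stack.bands:
            raise ValueError(f"stack is missing predictor layer {name!r}")
    layers = np.stack(
        [stack.band(n).astype(float) for n in model.predictors], axis=-1
    )
    h, w, p = layers.shape
    flat = layers.reshape(-1, p)
    valid = np.all(np.isfinite(flat), axis=1)
    out = np.full(h * w, np.nan)
    if valid.any():
        out[valid] = model._forest.predict(flat[valid])
    return out.reshape(h, w)


def map_microclimate(canopy_raster: np.ndarray, fit: ModelFit) -> np.ndarray:
    """Chain a selected plot-level linear model onto a canopy map.

    Per-pixel intercept + coefficient * value.  Ground-NDVI outputs are
    clipped to [-1, 1]; temperature outputs are not.  Undefined pixels
    propagate.
    """
    if fit.kind != "LM":
        raise ValueError(
            "mapping uses the selected linear relation; a smooth fit has "
            "no single slope"
        )
    canopy = np.asarray(canopy_raster, dtype=float)
    out = fit.intercept + fit.coefficient * canopy
    if "ndvi" in fit.response.lower():
        out = np.clip(out, -1.0, 1.0)
    return np.where(np.isfinite(canopy), out, np.nan)
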