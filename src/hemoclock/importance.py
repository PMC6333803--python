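"""Permutation feature importance and partial dependence for fitted models.

Permutation importance measures how much a performance metric degrades
when one feature column is shuffled, breaking its association with the
target while leaving its marginal distribution intact. Importance is
signed so that larger means more important: an MAE *increase* for
regressors, an F1/accuracy *decrease* for classifiers. Partial
dependence traces the mean model prediction as one feature is forced
across a grid with all other features at their observed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

METRICS = ("mae", "f1", "accuracy")


def _metric_value(metric: str, y_true: np.ndarray, y_out: np.ndarray) -> float:
    if metric == "mae":
        return float(np.mean(np.abs(y_out - y_true)))
    if metric == "accuracy":
        return float(np.mean(y_out == y_true))
    if metric == "f1":
        tp = float(((y_true == 1) & (y_out == 1)).sum())
        fp = float(((y_true == 0) & (y_out == 1)).sum())
        fn = float(((y_true == 1) & (y_out == 0)).sum())
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom > 0 else 0.0
    raise ConfigError(f"metric must be one of {METRICS}, got {metric!r}")


def permutation_importance(
    model,
    frame: pd.DataFrame,
    y_true,
    metric: str = "mae",
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +- SD performance drop per feature over seeded permutations.

    ``model`` needs a ``predict(frame)`` method and a ``features``
    attribute. The drop is permuted-minus-baseline for MAE and
    baseline-minus-permuted for F1/accuracy, so larger is always more
    important. Returns a frame with columns feature, importance_mean,
    importance_sd and rank (1 = most important).
    """
    if metric not in METRICS:
        raise ConfigError(f"metric must be one of {METRICS}, got {metric!r}")
    if n_repeats < 1:
        raise ConfigError(f"n_repeats must be >= 1, got {n_repeats}")
    if len(frame) < 2:
        raise DataError("permutation importance is meaningless on < 2 rows")
    y_true = np.asarray(y_true)
    rng = np.random.default_rng(seed)
    baseline = _metric_value(metric, y_true, model.predict(frame))
    sign = 1.0 if metric == "mae" else -1.0
    work = frame.copy()
    rows = []
    for feature in model.features:
        original = work[feature].to_numpy(copy=True)
        drops = np.empty(n_repeats)
        for rep in range(n_repeats):
            work[feature] = original[rng.permutation(len(work))]
            drops[rep] = sign * (_metric_value(metric, y_true, model.predict(work)) - baseline)
        work[feature] = original
        rows.append(
            {
                "feature": feature,
                "importance_mean": float(drops.mean()),
                "importance_sd": float(drops.std(ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    result = pd.DataFrame(rows).sort_values(
        ["importance_mean", "feature"], ascending=[False, True]
    )
    result["rank"] = np.arange(1, len(result) + 1)
    return result.reset_index(drop=True)


@dataclass
class PartialDependenceCurve:
    """Mean prediction per grid value of one feature."""

    feature: str
    grid: np.ndarray
    values: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.feature: self.grid, "mean_prediction": self.values})


def partial_dependence(
    model, feature: str, background: pd.DataFrame, grid=None, n_grid: int = 20
) -> PartialDependenceCurve:
    """Mean model prediction with ``feature`` forced to each grid value.

    The default grid is {0, 1} for binary features and ``n_grid``
    evenly spaced points over the observed range otherwise. For
    probabilistic classifiers the positive-class probability is traced.
    """
    if len(background) == 0:
        raise DataError("partial dependence requires a non-empty background")
    if feature not in background.columns:
        raise DataError(f"feature {feature!r} not in background columns")
    if grid is None:
        observed = background[feature].dropna().unique()
        if set(observed) <= {0, 1}:
            grid = np.array([0.0, 1.0])
        else:
            grid = np.linspace(observed.min(), observed.max(), n_grid)
    grid = np.sort(np.asarray(grid, dtype=float))
    predict = getattr(model, "predict_proba", None) or model.predict
    work = background.copy()
    values = np.empty(grid.size)
    for i, v in enumerate(grid):
        work[feature] = v
        values[i] = float(np.mean(predict(work)))
    return PartialDependenceCurve(feature, grid, values)
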