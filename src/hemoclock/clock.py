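"""Age prediction from blood markers, with the study's regression metrics.

The estimator contract is deliberately open: any regressor minimizing
mean absolute error satisfies it. Three kinds are provided — a small
fully connected network whose hidden width is chosen by k-fold
cross-validation, a gradient-boosted tree ensemble fitted under an
absolute-error loss, and an ordinary linear model. The clock is
normally trained on nonsmokers only, so that smokers' predicted age
reflects their marker-implied biological age; a guard refuses smoking
status as an input feature in that mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .arbitrage import FeatureSpace
from .errors import ConfigError, DataError, DegenerateInputError

NONSMOKERS_ONLY = "nonsmokers_only"
ALL_WITH_SMOKING = "all_with_smoking_feature"

DEFAULT_EPSILON = 10.0
MLP_WIDTH_GRID = (16, 32, 64)


@dataclass
class SplitSpec:
    """Train/test and cross-validation design."""

    train_fraction: float = 0.80
    cv_folds: int = 5
    seed: int = 0
    train_population: str = NONSMOKERS_ONLY

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.train_population not in (NONSMOKERS_ONLY, ALL_WITH_SMOKING):
            raise ConfigError(
                f"train_population must be {NONSMOKERS_ONLY!r} or "
                f"{ALL_WITH_SMOKING!r}, got {self.train_population!r}"
            )


def split_train_test(
    cohort: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split, stratified by age decade."""
    spec = spec or SplitSpec()
    spec.validate()
    if len(cohort) < 10:
        raise DataError(f"need at least 10 subjects to split, got {len(cohort)}")
    n_train = int(round(spec.train_fraction * len(cohort)))
    decade = (cohort["age"] // 10).to_numpy().copy()
    # merge strata too small to stratify on into the nearest populated decade
    values, counts = np.unique(decade, return_counts=True)
    viable = values[counts >= 2]
    if viable.size == 0:
        decade = np.zeros_like(decade)
    else:
        for value in values[counts < 2]:
            nearest = viable[np.argmin(np.abs(viable - value))]
            decade[decade == value] = nearest
    train, test = train_test_split(
        cohort,
        train_size=n_train,
        stratify=decade,
        random_state=spec.seed,
    )
    return train, test


class MarkerNormalizer:
    """Per-marker z-scoring with statistics fitted on the train set only."""

    def __init__(self) -> None:
        self.means: pd.Series | None = None
        self.sds: pd.Series | None = None

    def fit(self, train: pd.DataFrame, features: Sequence[str]) -> "MarkerNormalizer":
        block = train[list(features)]
        if block.isna().any().any():
            raise DataError("normalizer requires a train set complete on the features")
        sds = block.std(ddof=1)
        constant = sds[sds == 0].index.tolist()
        if constant:
            raise DegenerateInputError(
                f"markers with zero standard deviation in the train set: {constant}"
            )
        self.means, self.sds = block.mean(), sds
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise DataError("normalizer is not fitted")
        out = frame.copy()
        cols = self.means.index
        out[cols] = (out[cols] - self.means) / self.sds
        return out


def normalize_markers(
    train: pd.DataFrame, apply_to: pd.DataFrame, features: Sequence[str]
) -> pd.DataFrame:
    """Center and scale ``apply_to`` by train-set statistics (no leakage)."""
    return MarkerNormalizer().fit(train, features).transform(apply_to)


def _feature_list(features) -> list[str]:
    if isinstance(features, FeatureSpace):
        return list(features.markers)
    return list(features)


def _make_estimator(kind: str, spec: SplitSpec):
    if kind == "mlp":
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(
                        activation="relu",
                        alpha=1e-3,
                        max_iter=400,
                        early_stopping=True,
                        n_iter_no_change=15,
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
        grid = {"mlp__hidden_layer_sizes": [(w, w) for w in MLP_WIDTH_GRID]}
        return GridSearchCV(
            pipe,
            grid,
            scoring="neg_mean_absolute_error",
            cv=KFold(spec.cv_folds, shuffle=True, random_state=spec.seed),
            n_jobs=1,
        )
    if kind == "gbt":
        return HistGradientBoostingRegressor(
            loss="absolute_error", random_state=spec.seed
        )
    if kind == "linear":
        return LinearRegression()
    raise ConfigError(f"unknown estimator kind {kind!r}; use 'mlp', 'gbt' or 'linear'")


@dataclass
class AgePredictor:
    """A fitted age regressor plus the metadata needed to reuse it."""

    estimator: object
    features: list[str]
    kind: str
    spec: SplitSpec
    metadata: dict = field(default_factory=dict)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in frame.columns]
        if missing:
            raise DataError(f"cohort lacks model feature columns: {missing}")
        block = frame[self.features]
        if block.isna().any().any():
            raise DataError("cohort must be complete on the model features")
        return np.asarray(self.estimator.predict(block), dtype=float)

    def save(self, path) -> None:
        """Serialize the model; a JSON sidecar carries the metadata."""
        joblib.dump(self, path)
        sidecar = {
            "features": self.features,
            "kind": self.kind,
            "seed": self.spec.seed,
            "cv_folds": self.spec.cv_folds,
            "train_population": self.spec.train_population,
            **{k: v for k, v in self.metadata.items() if _jsonable(v)},
        }
        with open(f"{path}.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(path) -> "AgePredictor":
        return joblib.load(path)


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def train_age_model(
    train: pd.DataFrame,
    features,
    spec: SplitSpec | None = None,
    estimator: str = "mlp",
) -> AgePredictor:
    """Fit an age regressor on the train cohort.

    In ``nonsmokers_only`` mode the train set must contain no smokers
    and smoking status must not appear among the features (it would be
    constant and, worse, would contaminate the biological-age readout).
    """
    spec = spec or SplitSpec()
    spec.validate()
    features = _feature_list(features)
    if spec.train_population == NONSMOKERS_ONLY:
        if "smoking" in features:
            raise ConfigError(
                "smoking status cannot be an input feature when training on "
                f"nonsmokers only; use train_population={ALL_WITH_SMOKING!r}"
            )
        if (train["smoking"] != 0).any():
            raise DataError("nonsmokers_only training set contains smokers")
    block = train[features]
    if block.isna().any().any():
        raise DataError("train set must be complete on the features")
    model = _make_estimator(estimator, spec)
    model.fit(block, train["age"].to_numpy(dtype=float))
    metadata: dict = {"n_train": len(train), "loss": "mean_absolute_error"}
    if isinstance(model, GridSearchCV):
        metadata["cv_best_params"] = model.best_params_
        metadata["cv_mae"] = float(-model.best_score_)
        model = model.best_estimator_
    return AgePredictor(model, features, estimator, spec, metadata)


def predict_age(model: AgePredictor, cohort: pd.DataFrame) -> pd.DataFrame:
    """Predict ages; returns a PredictionSet carrying age/sex/smoking."""
    y_pred = model.predict(cohort)
    out = pd.DataFrame(
        {
            "y_true": cohort["age"].to_numpy(dtype=float),
            "y_pred": y_pred,
            "age": cohort["age"].to_numpy(),
            "sex": cohort["sex"].to_numpy(),
            "smoking": cohort["smoking"].to_numpy(),
        },
        index=cohort.index,
    )
    if "id" in cohort.columns:
        out.insert(0, "id", cohort["id"].to_numpy())
    return out


@dataclass
class RegressionReport:
    """r, R^2, MAE (years) and epsilon-accuracy of a prediction set."""

    r: float | None
    r2: float | None
    mae: float
    epsilon_accuracy: float
    epsilon: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "r2": self.r2,
            "mae": self.mae,
            "epsilon": self.epsilon,
            "epsilon_accuracy": self.epsilon_accuracy,
            "n": self.n,
        }


def regression_metrics(
    pred: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> RegressionReport:
    """Pearson r, coefficient of determination, MAE and eps-accuracy.

    The epsilon interval is closed: a prediction exactly epsilon years
    off counts as correct. With zero variance in the true ages, r and
    R^2 are undefined and reported as None.
    """
    y = pred["y_true"].to_numpy(dtype=float)
    yhat = pred["y_pred"].to_numpy(dtype=float)
    if len(y) < 2:
        raise DataError(f"need >= 2 samples for regression metrics, got {len(y)}")
    if np.isnan(y).any() or np.isnan(yhat).any():
        raise DataError("prediction set contains missing values")
    mae = float(np.mean(np.abs(yhat - y)))
    eps_acc = float(np.mean(np.abs(yhat - y) <= epsilon))
    sy = y - y.mean()
    syh = yhat - yhat.mean()
    ss_y = float(sy @ sy)
    ss_yh = float(syh @ syh)
    if ss_y == 0.0:
        r = r2 = None
    else:
        r = float(sy @ syh / np.sqrt(ss_y * ss_yh)) if ss_yh > 0.0 else None
        r2 = float(1.0 - ((yhat - y) @ (yhat - y)) / ss_y)
    return RegressionReport(r, r2, mae, eps_acc, float(epsilon), len(y))
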