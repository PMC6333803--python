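"""Smoking-status classification from blood markers and sex.

Smoker is the positive class throughout. Metrics follow the usual
confusion-count definitions (accuracy, precision, recall and their
harmonic mean F1); age-stratified confusion matrices localize where the
classifier fails, the analysis that showed most smoking-status errors
occur in older subjects once the smoking signature fades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .arbitrage import FeatureSpace
from .clock import MLP_WIDTH_GRID, SplitSpec, _feature_list
from .errors import ConfigError, DataError

#: Default age bins: <31, 31-40, 41-50, 51-60, 61-70, >70 (integer ages).
DEFAULT_AGE_BINS = ((-np.inf, 30), (31, 40), (41, 50), (51, 60), (61, 70), (71, np.inf))


def _bin_label(lo: float, hi: float) -> str:
    if np.isinf(lo) and np.isinf(hi):
        return "all"
    if np.isinf(lo):
        return f"<{int(hi) + 1}"
    if np.isinf(hi):
        return f">{int(lo) - 1}"
    return f"{int(lo)}-{int(hi)}"


def _make_classifier(kind: str, spec: SplitSpec):
    if kind == "mlp":
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
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
            scoring="f1",
            cv=StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed),
            n_jobs=1,
        )
    if kind == "gbt":
        return HistGradientBoostingClassifier(random_state=spec.seed)
    if kind == "linear":
        return Pipeline(
            [("scale", StandardScaler()), ("logit", LogisticRegression(max_iter=1000))]
        )
    raise ConfigError(f"unknown estimator kind {kind!r}; use 'mlp', 'gbt' or 'linear'")


@dataclass
class SmokingClassifier:
    """A fitted probabilistic smoking-status classifier."""

    estimator: object
    features: list[str]
    kind: str
    spec: SplitSpec
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in frame.columns]
        if missing:
            raise DataError(f"cohort lacks model feature columns: {missing}")
        block = frame[self.features]
        if block.isna().any().any():
            raise DataError("cohort must be complete on the model features")
        return np.asarray(self.estimator.predict_proba(block)[:, 1], dtype=float)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(frame) >= self.threshold).astype(np.int64)


def train_smoking_model(
    train: pd.DataFrame,
    features,
    spec: SplitSpec | None = None,
    estimator: str = "mlp",
) -> SmokingClassifier:
    """Fit a smoking classifier; smoking itself is refused as a feature."""
    spec = spec or SplitSpec()
    spec.validate()
    features = _feature_list(features)
    if "smoking" in features:
        raise ConfigError("smoking status is the label and cannot be an input feature")
    block = train[features]
    if block.isna().any().any():
        raise DataError("train set must be complete on the features")
    model = _make_classifier(estimator, spec)
    model.fit(block, train["smoking"].to_numpy(dtype=np.int64))
    metadata: dict = {"n_train": len(train), "loss": "binary_cross_entropy"}
    if isinstance(model, GridSearchCV):
        metadata["cv_best_params"] = model.best_params_
        metadata["cv_f1"] = float(model.best_score_)
        model = model.best_estimator_
    return SmokingClassifier(model, features, estimator, spec, metadata=metadata)


@dataclass
class ClassificationReport:
    """Confusion counts and the derived metrics; None where undefined."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def classification_metrics(y_true, y_pred) -> ClassificationReport:
    """Accuracy, precision, recall and F1 with smoker as positive class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise DataError("classification_metrics requires non-empty labels")
    if y_true.shape != y_pred.shape:
        raise DataError("label vectors must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise DataError("labels must be binary (0/1)")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    accuracy = (tp + tn) / y_true.size
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationReport(tp, fp, fn, tn, accuracy, precision, recall, f1)


@dataclass
class AgeGroupConfusion:
    """Per-age-bin confusion counts, row percentages and error rates."""

    table: pd.DataFrame  # indexed by bin label

    @property
    def global_report(self) -> ClassificationReport:
        t = self.table[["tp", "fp", "fn", "tn"]].sum()
        counts = dict(tp=int(t.tp), fp=int(t.fp), fn=int(t.fn), tn=int(t.tn))
        n = sum(counts.values())
        report = classification_metrics(
            np.concatenate([np.ones(counts["tp"] + counts["fn"], dtype=int),
                            np.zeros(counts["fp"] + counts["tn"], dtype=int)]),
            np.concatenate([np.ones(counts["tp"], dtype=int),
                            np.zeros(counts["fn"], dtype=int),
                            np.ones(counts["fp"], dtype=int),
                            np.zeros(counts["tn"], dtype=int)]),
        ) if n else None
        return report


def confusion_by_age_group(
    y_true, y_pred, ages, bins=DEFAULT_AGE_BINS
) -> AgeGroupConfusion:
    """2x2 confusion counts, percentages and error rate per age bin.

    Empty bins are reported with zero counts rather than dropped; row
    percentages normalize each true class within the bin.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    ages = np.asarray(ages, dtype=float)
    if np.isnan(ages).any():
        raise DataError("ages must be present for every row")
    rows = []
    for lo, hi in bins:
        mask = (ages >= lo) & (ages <= hi)
        t, p = y_true[mask], y_pred[mask]
        tp = int(((t == 1) & (p == 1)).sum())
        fp = int(((t == 0) & (p == 1)).sum())
        fn = int(((t == 1) & (p == 0)).sum())
        tn = int(((t == 0) & (p == 0)).sum())
        n = tp + fp + fn + tn
        n_smoker, n_nonsmoker = tp + fn, fp + tn
        rows.append(
            {
                "age_group": _bin_label(lo, hi),
                "n": n,
                "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "pct_smoker_correct": 100.0 * tp / n_smoker if n_smoker else np.nan,
                "pct_smoker_missed": 100.0 * fn / n_smoker if n_smoker else np.nan,
                "pct_nonsmoker_correct": 100.0 * tn / n_nonsmoker if n_nonsmoker else np.nan,
                "pct_nonsmoker_missed": 100.0 * fp / n_nonsmoker if n_nonsmoker else np.nan,
                "error_rate": (fp + fn) / n if n else np.nan,
            }
        )
    return AgeGroupConfusion(pd.DataFrame(rows).set_index("age_group"))
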