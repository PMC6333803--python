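"""Age-acceleration analysis: log2 aging ratios, stratified summaries,
cardiovascular risk quadrants and robust marker-age correlation.

The central statistic is the per-sample log2 aging ratio
log2(predicted age / chronological age): 0 means on-clock, 1 means
predicted twice as old, -1 half as old. Smokers and nonsmokers are
compared within (age group x sex) cells by a two-tailed Mann-Whitney
test, rejecting at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError
from .smoking import DEFAULT_AGE_BINS, _bin_label

ALPHA = 0.05
_EXACT_MAX_N = 50

CHOLESTEROL_RATIO_THRESHOLD = 4.0
GLUCOSE_THRESHOLD_MMOL_L = 5.0


def log2_aging_ratio(y_true, y_pred) -> np.ndarray:
    """Per-sample log2(predicted age / chronological age).

    Chronological ages must be positive; nonpositive *predicted* ages
    (possible from an unconstrained regressor) yield NaN so the caller
    can exclude and count them.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if (y <= 0).any():
        raise DataError("chronological ages must be positive")
    out = np.full(y.shape, np.nan)
    valid = yhat > 0
    out[valid] = np.log2(yhat[valid] / y[valid])
    return out


def attach_ratios(pred: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Add a ``log2_ratio`` column to a prediction set.

    Returns (frame, number of samples excluded for nonpositive
    predicted age); excluded rows carry NaN ratios.
    """
    out = pred.copy()
    out["log2_ratio"] = log2_aging_ratio(out["y_true"], out["y_pred"])
    return out, int(out["log2_ratio"].isna().sum())


def _age_group_labels(ages, bins) -> pd.Categorical:
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    edges = [lo for lo, _ in bins] + [np.inf]
    idx = np.searchsorted(np.asarray(edges[1:-1]), np.asarray(ages, dtype=float), side="right")
    return pd.Categorical([labels[i] for i in idx], categories=labels, ordered=True)


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Mann-Whitney p; exact for small tie-free samples."""
    ties = len(np.unique(np.concatenate([a, b]))) < (len(a) + len(b))
    method = "exact" if (len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def group_aging_summary(
    pred: pd.DataFrame, bins=DEFAULT_AGE_BINS, extra_keys: list[str] | None = None
) -> pd.DataFrame:
    """Mean/SD/n of the log2 aging ratio per (age group, sex, smoking).

    Each (age group, sex) pair with at least one smoker and one
    nonsmoker gets a two-tailed Mann-Whitney p comparing the two ratio
    distributions (attached to both rows) and a significance flag at
    p < 0.05; cells where the comparison is undefined carry NaN.
    Empty cells are emitted with n = 0. ``extra_keys`` prepends extra
    stratification columns (used for the risk-quadrant table).
    """
    if "log2_ratio" not in pred.columns:
        pred, _ = attach_ratios(pred)
    frame = pred.dropna(subset=["log2_ratio"]).copy()
    frame["age_group"] = _age_group_labels(frame["age"], bins)
    keys = (extra_keys or []) + ["age_group", "sex", "smoking"]
    grouped = frame.groupby(keys, observed=False)["log2_ratio"]
    table = grouped.agg(n="count", mean_log2_ratio="mean", sd_log2_ratio=lambda s: s.std(ddof=1))
    table = table.reset_index()

    pair_keys = (extra_keys or []) + ["age_group", "sex"]
    pvalues: dict[tuple, float] = {}
    for key, cell in frame.groupby(pair_keys, observed=False):
        smokers = cell.loc[cell["smoking"] == 1, "log2_ratio"].to_numpy()
        nonsmokers = cell.loc[cell["smoking"] == 0, "log2_ratio"].to_numpy()
        if len(smokers) >= 1 and len(nonsmokers) >= 1:
            pvalues[key if isinstance(key, tuple) else (key,)] = _mann_whitney_p(
                smokers, nonsmokers
            )
    table["mw_p"] = [
        pvalues.get(tuple(row[k] for k in pair_keys), np.nan) for _, row in table.iterrows()
    ]
    table["significant"] = table["mw_p"] < ALPHA
    return table


@dataclass(frozen=True)
class RiskGroup:
    """Cardiovascular risk quadrant from cholesterol ratio and glucose."""

    cholesterol_ratio: float
    fasting_glucose: float

    @property
    def high_ratio(self) -> bool:
        return self.cholesterol_ratio > CHOLESTEROL_RATIO_THRESHOLD

    @property
    def high_glucose(self) -> bool:
        return self.fasting_glucose > GLUCOSE_THRESHOLD_MMOL_L

    @property
    def label(self) -> str:
        ratio = "ratio>4" if self.high_ratio else "ratio<=4"
        glucose = "glucose>5" if self.high_glucose else "glucose<=5"
        return f"{ratio},{glucose}"


def assign_risk_groups(
    cohort: pd.DataFrame,
    total_col: str = "total_cholesterol",
    hdl_col: str = "hdl_cholesterol",
    glucose_col: str = "fasting_glucose",
) -> tuple[pd.Series, int]:
    """Quadrant label per row from (total/HDL cholesterol, glucose).

    Thresholds: cholesterol ratio > 4 and fasting glucose > 5 mmol/L
    (complements take <=). Rows with HDL <= 0 or any of the three
    markers missing are excluded (NaN label) and counted.
    """
    total = cohort[total_col].to_numpy(dtype=float)
    hdl = cohort[hdl_col].to_numpy(dtype=float)
    glucose = cohort[glucose_col].to_numpy(dtype=float)
    valid = ~(np.isnan(total) | np.isnan(hdl) | np.isnan(glucose)) & (hdl > 0)
    labels = pd.Series(pd.NA, index=cohort.index, dtype="object")
    ratio = np.divide(total, hdl, out=np.full_like(total, np.nan), where=hdl > 0)
    for i in np.flatnonzero(valid):
        labels.iloc[i] = RiskGroup(ratio[i], glucose[i]).label
    return labels, int((~valid).sum())


def risk_group_aging_summary(
    pred: pd.DataFrame, risk_labels: pd.Series, bins=DEFAULT_AGE_BINS
) -> pd.DataFrame:
    """Group aging summary with the risk quadrant as an extra key.

    Rows whose risk quadrant could not be assigned are dropped.
    """
    frame = pred.copy()
    frame["risk_group"] = risk_labels.reindex(frame.index)
    frame = frame.dropna(subset=["risk_group"])
    return group_aging_summary(frame, bins=bins, extra_keys=["risk_group"])


def biweight_midcorrelation(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation of two vectors.

    Median-centered values are downweighted by Tukey biweights with
    tuning constant ``c`` (default 9) times the raw median absolute
    deviation; observations at or beyond c MADs get zero weight. Raises
    :class:`DegenerateInputError` when either MAD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise DataError(f"need at least 3 observations, got {x.size}")
    med_x, med_y = np.median(x), np.median(y)
    mad_x = np.median(np.abs(x - med_x))
    mad_y = np.median(np.abs(y - med_y))
    if mad_x == 0 or mad_y == 0:
        raise DegenerateInputError(
            "zero median absolute deviation; biweight midcorrelation is undefined"
        )
    u = (x - med_x) / (c * mad_x)
    v = (y - med_y) / (c * mad_y)
    w_x = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    w_y = np.where(np.abs(v) < 1, (1 - v**2) ** 2, 0.0)
    a = (x - med_x) * w_x
    b = (y - med_y) * w_y
    return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))


def marker_age_bicor(cohort: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Biweight midcorrelation of each marker with chronological age."""
    rows = []
    for marker in markers:
        sub = cohort.dropna(subset=[marker])
        rows.append(
            {
                "marker": marker,
                "bicor": biweight_midcorrelation(
                    sub[marker].to_numpy(), sub["age"].to_numpy(dtype=float)
                ),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows).sort_values("bicor", ascending=False).reset_index(drop=True)
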