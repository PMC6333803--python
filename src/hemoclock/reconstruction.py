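"""Missing-marker reconstruction by per-marker linear regression.

A marker with missing values is regressed (ordinary least squares) on a
set of fully observed predictor markers plus age and sex, over the
subjects where it was measured; the fitted model then fills the missing
cells deterministically. Observed values are never overwritten, and a
per-cell provenance flag distinguishes measured from reconstructed
entries. Markers are filled in ascending order of missingness so that
earlier reconstructions can serve as predictors for later ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import cross_val_score

from .arbitrage import FeatureSpace
from .errors import DataError

MIN_FIT_ROWS = 100
_BASE_PREDICTORS = ["age", "sex"]


@dataclass
class ImputationModel:
    """A fitted per-marker regression: target ~ predictors + age + sex."""

    target: str
    predictors: list[str]
    coefficients: np.ndarray  # [intercept, *predictor coefs]
    fit_n: int
    fit_fraction: float
    oos_r2: float | None = None

    def design(self, frame: pd.DataFrame) -> np.ndarray:
        return frame[self.predictors].to_numpy(dtype=float)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        x = self.design(frame)
        return self.coefficients[0] + x @ self.coefficients[1:]


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns implicated in a rank deficiency (QR pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def fit_marker_regression(
    cohort: pd.DataFrame,
    target: str,
    predictors: list[str],
    min_rows: int = MIN_FIT_ROWS,
    compute_oos_r2: bool = False,
) -> ImputationModel:
    """OLS fit of ``target`` on ``predictors`` + age + sex.

    Uses the subjects where the target and every predictor are
    observed. Raises :class:`DataError` if fewer than ``min_rows`` such
    subjects exist, or if the design is rank-deficient (the message
    names the collinear predictors).
    """
    if target in predictors:
        raise DataError(f"target {target!r} cannot be its own predictor")
    design_cols = [p for p in predictors if p not in _BASE_PREDICTORS] + _BASE_PREDICTORS
    rows = cohort.dropna(subset=[target, *design_cols])
    if len(rows) < min_rows:
        raise DataError(
            f"marker {target!r}: only {len(rows)} complete rows available to fit "
            f"(need >= {min_rows})"
        )
    x = rows[design_cols].to_numpy(dtype=float)
    y = rows[target].to_numpy(dtype=float)
    with_intercept = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(with_intercept) < with_intercept.shape[1]:
        bad = _collinear_columns(with_intercept, ["intercept", *design_cols])
        raise DataError(
            f"marker {target!r}: rank-deficient design; collinear predictors: {bad}"
        )
    ols = LinearRegression().fit(x, y)
    oos_r2 = None
    if compute_oos_r2:
        oos_r2 = float(np.mean(cross_val_score(LinearRegression(), x, y, cv=5, scoring="r2")))
    return ImputationModel(
        target=target,
        predictors=design_cols,
        coefficients=np.concatenate([[ols.intercept_], ols.coef_]),
        fit_n=len(rows),
        fit_fraction=len(rows) / len(cohort),
        oos_r2=oos_r2,
    )


@dataclass
class ReconstructionResult:
    """Filled cohort plus provenance and the cells left unfillable."""

    cohort: pd.DataFrame
    #: boolean frame (rows x modeled markers); True = reconstructed cell
    provenance: pd.DataFrame
    #: per-marker count of cells that stayed missing (missing predictor)
    unfilled: dict[str, int] = field(default_factory=dict)

    @property
    def n_unfilled(self) -> int:
        return sum(self.unfilled.values())


def reconstruct_missing(
    cohort: pd.DataFrame, models: list[ImputationModel]
) -> ReconstructionResult:
    """Fill missing cells of the modeled markers, in model order.

    Observed values are never overwritten. A cell whose predictors are
    not all available (observed or previously reconstructed) is left
    missing and counted in ``unfilled``.
    """
    filled = cohort.copy()
    provenance = pd.DataFrame(
        False, index=cohort.index, columns=[m.target for m in models]
    )
    unfilled: dict[str, int] = {}
    for model in models:
        missing = filled[model.target].isna()
        predictors_ok = filled[model.predictors].notna().all(axis=1)
        fillable = missing & predictors_ok
        if fillable.any():
            filled.loc[fillable, model.target] = model.predict(filled.loc[fillable])
            provenance.loc[fillable, model.target] = True
        unfilled[model.target] = int((missing & ~predictors_ok).sum())
    return ReconstructionResult(cohort=filled, provenance=provenance, unfilled=unfilled)


def plan_reconstruction(
    cohort: pd.DataFrame,
    complete_markers: list[str],
    targets: list[str],
    min_rows: int = MIN_FIT_ROWS,
    compute_oos_r2: bool = False,
) -> list[ImputationModel]:
    """Fit one regression per target, ordered by ascending missingness."""
    ordered = sorted(targets, key=lambda t: (cohort[t].isna().mean(), t))
    return [
        fit_marker_regression(
            cohort, t, complete_markers, min_rows=min_rows, compute_oos_r2=compute_oos_r2
        )
        for t in ordered
    ]


def expand_feature_space(
    cohort: pd.DataFrame,
    space: FeatureSpace,
    candidates: list[str] | None = None,
    fit_fraction_range: tuple[float, float] = (0.30, 0.60),
    min_rows: int = MIN_FIT_ROWS,
) -> tuple[pd.DataFrame, FeatureSpace, ReconstructionResult]:
    """Reconstruct extra markers on a feature space's eligible subjects.

    Restricts the cohort to complete cases of ``space`` and picks as
    reconstruction targets the candidate markers observed for a
    fraction of those subjects inside ``fit_fraction_range`` (default
    30-60%, the share of the feature space available to fit each
    marker regression) with at least ``min_rows`` observed rows.
    Returns (eligible sub-cohort after filling, expanded space,
    result); the expanded space contains the original markers plus
    every candidate that ends fully observed. Which markers qualify
    can differ between nested feature spaces when missingness is
    structured, so larger spaces may gain more markers.
    """
    from .cohort import marker_names

    sub = cohort.dropna(subset=list(space.markers))
    if candidates is None:
        candidates = [m for m in marker_names(cohort) if m not in space.markers]
    lo, hi = fit_fraction_range
    targets = []
    for m in candidates:
        observed = sub[m].notna().mean()
        if lo <= observed <= hi and sub[m].notna().sum() >= min_rows:
            targets.append(m)
    models = plan_reconstruction(
        sub, list(space.markers), targets, min_rows=min_rows, compute_oos_r2=True
    )
    result = reconstruct_missing(sub, models)
    completed = [t for t in targets if result.cohort[t].notna().all()]
    expanded = FeatureSpace(tuple(space.markers) + tuple(sorted(completed)), len(sub))
    return result.cohort, expanded, result
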