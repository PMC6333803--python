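"""Arbitrage feature importance over ensembles of random-forest age models.

Many tree-ensemble regressors are trained on distinct marker subsets
("feature spaces"); each model i contributes its per-marker mean
decrease accuracy q_i, operationalized as permutation importance on a
held-out split, weighted by the inverse of its own mean absolute error:

    FI(marker) = sum over models containing the marker of q_i / MAE_i

Markers are ranked by FI, and nested feature sets are then chosen at
the sizes where the number of complete-case subjects drops sharply
("knee" points), trading feature-set size against available samples.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .cohort import marker_names
from .errors import DataError, DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_N_SPACES = 320
DEFAULT_N_TREES = 80
MIN_ELIGIBLE = 50


@dataclass(frozen=True)
class FeatureSpace:
    """An ordered marker subset with its complete-case sample count."""

    markers: tuple[str, ...]
    eligible_n: int

    def __post_init__(self) -> None:
        if not self.markers:
            raise DataError("FeatureSpace.markers must be non-empty")
        if self.eligible_n < 0:
            raise DataError("FeatureSpace.eligible_n must be >= 0")


@dataclass
class ArbitrageModelRecord:
    """One fitted ensemble: its space, held-out MAE and importances."""

    space: FeatureSpace
    mae: float
    importance: dict[str, float]
    n_train: int = 0
    n_test: int = 0
    n_trees: int = 0


def eligible_count(cohort: pd.DataFrame, markers) -> int:
    """Number of subjects with every listed marker observed."""
    return int(cohort[list(markers)].notna().all(axis=1).sum())


def make_space(cohort: pd.DataFrame, markers) -> FeatureSpace:
    return FeatureSpace(tuple(markers), eligible_count(cohort, markers))


def _comissingness_blocks(observed: pd.DataFrame) -> list[tuple[str, ...]]:
    """Distinct observed-marker patterns, as marker tuples.

    Each subject's set of observed markers is one candidate block; the
    maximal marker sets shared by groups of subjects are exactly the
    distinct rows of the observation-indicator matrix.
    """
    patterns = observed.drop_duplicates()
    blocks = []
    for _, row in patterns.iterrows():
        markers = tuple(observed.columns[row.to_numpy(dtype=bool)])
        if markers:
            blocks.append(markers)
    return sorted(set(blocks), key=lambda b: (-len(b), b))


def enumerate_feature_spaces(
    cohort: pd.DataFrame,
    candidates: list[str] | None = None,
    n_spaces: int = DEFAULT_N_SPACES,
    min_eligible: int = MIN_ELIGIBLE,
    seed: int = 0,
) -> list[FeatureSpace]:
    """Construct ``n_spaces`` distinct feature spaces.

    Spaces are (a) the cohort's co-missingness blocks (maximal marker
    sets sharing fully observed subjects) and (b) seeded random marker
    subsets at sizes 5..len(candidates) (1.. for small candidate sets),
    all filtered to ``eligible_n >= min_eligible``, until ``n_spaces``
    distinct spaces exist. Raises :class:`DataError` naming the maximum
    attainable when fewer distinct subsets exist.
    """
    if n_spaces < 1:
        raise DataError(f"n_spaces must be >= 1, got {n_spaces}")
    if candidates is None:
        candidates = marker_names(cohort)
    candidates = list(candidates)
    k = len(candidates)
    if k < 2:
        raise DataError(f"need >= 2 candidate markers, got {k}")

    max_subsets = (1 << k) - 1
    if max_subsets < n_spaces:
        raise DataError(
            f"cannot build {n_spaces} distinct feature spaces from {k} markers; "
            f"maximum attainable is {max_subsets}"
        )

    observed = cohort[candidates].notna()
    obs = observed.to_numpy(dtype=bool)
    col_index = {m: i for i, m in enumerate(candidates)}

    def n_eligible(markers: tuple[str, ...]) -> int:
        cols = [col_index[m] for m in markers]
        return int(obs[:, cols].all(axis=1).sum())

    chosen: dict[tuple[str, ...], int] = {}
    for block in _comissingness_blocks(observed):
        if len(chosen) >= n_spaces:
            break
        ne = n_eligible(block)
        if ne >= min_eligible:
            chosen[block] = ne

    rng = np.random.default_rng(seed)
    lo_size = 1 if k <= 5 else 5
    attempts, max_attempts = 0, max(500 * n_spaces, 10_000)
    while len(chosen) < n_spaces and attempts < max_attempts:
        attempts += 1
        size = int(rng.integers(lo_size, k + 1))
        subset = tuple(sorted(rng.choice(candidates, size=size, replace=False)))
        if subset in chosen:
            continue
        ne = n_eligible(subset)
        if ne >= min_eligible:
            chosen[subset] = ne

    if len(chosen) < n_spaces and k <= 20:
        # exhaustive sweep for small candidate sets
        for size in range(1, k + 1):
            for combo in itertools.combinations(sorted(candidates), size):
                if len(chosen) >= n_spaces:
                    break
                if combo in chosen:
                    continue
                ne = n_eligible(combo)
                if ne >= min_eligible:
                    chosen[combo] = ne

    if len(chosen) < n_spaces:
        raise DataError(
            f"only {len(chosen)} distinct feature spaces with eligible_n >= "
            f"{min_eligible} were found; requested {n_spaces}"
        )
    spaces = [FeatureSpace(m, ne) for m, ne in chosen.items()]
    return spaces[:n_spaces]


def _batched_permutation_mae_increase(
    forest,
    x_test: np.ndarray,
    y_test: np.ndarray,
    baseline_mae: float,
    n_repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-decrease-accuracy q per feature: MAE increase when permuted.

    All (feature x repeat) permuted copies of the test block are
    stacked and scored in a single ensemble predict call; calling
    predict per permutation is ~50x slower at these test-set sizes.
    """
    n, k = x_test.shape
    stacked = np.tile(x_test, (k * n_repeats, 1))
    for j in range(k):
        for rep in range(n_repeats):
            block = slice((j * n_repeats + rep) * n, (j * n_repeats + rep + 1) * n)
            stacked[block, j] = x_test[rng.permutation(n), j]
    errors = np.abs(forest.predict(stacked) - np.tile(y_test, k * n_repeats))
    per_permutation = errors.reshape(k * n_repeats, n).mean(axis=1)
    return per_permutation.reshape(k, n_repeats).mean(axis=1) - baseline_mae


def fit_arbitrage_ensemble(
    cohort: pd.DataFrame,
    spaces: list[FeatureSpace],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    min_eligible: int = MIN_ELIGIBLE,
    n_permutation_repeats: int = 5,
) -> list[ArbitrageModelRecord]:
    """Train one random-forest age regressor per feature space.

    Each model is fitted on the complete cases of its space, split
    80/20 (seeded per space index); MAE_i is the held-out mean absolute
    error and q_i the permutation importance of each marker on the
    held-out split. Spaces with fewer than ``min_eligible`` complete
    cases are skipped with a logged warning.
    """
    records: list[ArbitrageModelRecord] = []
    for index, space in enumerate(spaces):
        cols = list(space.markers)
        complete = cohort.dropna(subset=cols)
        if len(complete) < min_eligible:
            message = (
                f"skipping feature space {index} ({len(cols)} markers): "
                f"{len(complete)} complete cases < {min_eligible}"
            )
            logger.warning(message)
            warnings.warn(message, stacklevel=2)
            continue
        space_seed = (seed * 100_003 + index) % (2**31)
        x_tr, x_te, y_tr, y_te = train_test_split(
            complete[cols],
            complete["age"].to_numpy(dtype=float),
            test_size=0.2,
            random_state=space_seed,
        )
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=2,
            max_features="sqrt",
            random_state=space_seed,
            n_jobs=1,
        )
        forest.fit(x_tr, y_tr)
        x_te = x_te.to_numpy(dtype=float)
        mae = float(np.mean(np.abs(forest.predict(x_te) - y_te)))
        q = _batched_permutation_mae_increase(
            forest, x_te, y_te, mae, n_permutation_repeats,
            np.random.default_rng(space_seed),
        )
        importance = {m: float(v) for m, v in zip(cols, q)}
        records.append(
            ArbitrageModelRecord(
                space=space,
                mae=mae,
                importance=importance,
                n_train=len(x_tr),
                n_test=len(x_te),
                n_trees=n_trees,
            )
        )
    return records


def arbitrage_fi(records: list[ArbitrageModelRecord]) -> pd.DataFrame:
    """Aggregate FI = sum_i q_i / MAE_i per marker over all records.

    Returns a frame indexed 0..m-1 with columns ``marker``, ``fi`` and
    ``n_models``, sorted by descending FI then ascending marker name.
    """
    if not records:
        raise DataError("arbitrage_fi requires at least one model record")
    fi: dict[str, float] = {}
    n_models: dict[str, int] = {}
    for index, record in enumerate(records):
        if record.mae == 0:
            raise DegenerateInputError(
                f"record {index} has MAE = 0; the arbitrage weight q_i/MAE_i is undefined"
            )
        for marker in record.space.markers:
            if marker not in record.importance:
                raise DataError(
                    f"record {index} lacks an importance value for marker {marker!r}"
                )
            fi[marker] = fi.get(marker, 0.0) + record.importance[marker] / record.mae
            n_models[marker] = n_models.get(marker, 0) + 1
    frame = pd.DataFrame(
        {"marker": list(fi), "fi": list(fi.values()), "n_models": [n_models[m] for m in fi]}
    )
    return frame.sort_values(["fi", "marker"], ascending=[False, True]).reset_index(drop=True)


def select_feature_sets(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    n_sets: int = 3,
    drop_fraction: float = 0.10,
) -> list[FeatureSpace]:
    """Choose nested feature sets along the FI ranking.

    Markers are added greedily in descending FI (ties broken by name);
    the complete-case count of each prefix is recorded. A prefix size s
    is a knee when adding the next marker loses more than
    ``drop_fraction`` of the eligible subjects. The ``n_sets`` knees
    with the largest eligible_n are returned (topped up, if there are
    fewer knees, with the sizes maximizing eligible_n x size), sorted
    by size; the sets are nested prefixes of one ranking by
    construction.
    """
    if scores.empty:
        raise DataError("select_feature_sets requires non-empty scores")
    ranked = scores.sort_values(["fi", "marker"], ascending=[False, True])["marker"].tolist()
    obs = cohort[ranked].notna().to_numpy(dtype=bool)
    prefix_ok = np.cumprod(obs, axis=1, dtype=bool)
    eligible = prefix_ok.sum(axis=0).astype(int)  # eligible[s-1] for prefix size s
    k = len(ranked)

    knees = [
        s
        for s in range(1, k)
        if eligible[s] < (1.0 - drop_fraction) * eligible[s - 1]
    ]
    knees.sort(key=lambda s: (-eligible[s - 1], -s))
    sizes = knees[:n_sets]
    if len(sizes) < n_sets:
        rest = [s for s in range(1, k + 1) if s not in sizes]
        rest.sort(key=lambda s: (-int(eligible[s - 1]) * s, -eligible[s - 1]))
        sizes.extend(rest[: n_sets - len(sizes)])
    sizes = sorted(sizes)
    return [FeatureSpace(tuple(ranked[:s]), int(eligible[s - 1])) for s in sizes]
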