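"""Arbitrage FI: formula oracle, space construction, planted recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoclock import DataError, DegenerateInputError
from hemoclock.arbitrage import (
    ArbitrageModelRecord,
    FeatureSpace,
    arbitrage_fi,
    enumerate_feature_spaces,
    fit_arbitrage_ensemble,
    make_space,
    select_feature_sets,
)
from tests.conftest import make_frame


def record(markers, mae, importance):
    return ArbitrageModelRecord(
        space=FeatureSpace(tuple(markers), 100), mae=mae, importance=importance
    )


def fi_oracle(records):
    """Plain-loop reference implementation of FI = sum q_i / MAE_i."""
    out = {}
    for rec in records:
        for marker in rec.space.markers:
            out[marker] = out.get(marker, 0.0) + rec.importance[marker] / rec.mae
    return out


class TestArbitrageFI:
    def test_hand_computed_examples(self):
        one = arbitrage_fi([record(["a"], 2.0, {"a": 0.5})])
        assert one.loc[0, "fi"] == pytest.approx(0.25)
        two = arbitrage_fi(
            [record(["a"], 3.0, {"a": 0.3}), record(["a"], 4.0, {"a": 0.2})]
        )
        assert two.loc[0, "fi"] == pytest.approx(0.3 / 3 + 0.2 / 4)
        zero = arbitrage_fi([record(["a", "b"], 5.0, {"a": 0.0, "b": 0.0})])
        assert (zero["fi"] == 0.0).all()

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            markers = [f"m{j}" for j in range(rng.integers(1, 6))]
            records = [
                record(
                    sub := sorted(
                        rng.choice(markers, size=rng.integers(1, len(markers) + 1),
                                   replace=False)
                    ),
                    float(rng.uniform(0.5, 10)),
                    {m: float(rng.normal()) for m in sub},
                )
                for _ in range(rng.integers(1, 8))
            ]
            got = arbitrage_fi(records).set_index("marker")["fi"]
            want = fi_oracle(records)
            for marker, value in want.items():
                assert got[marker] == pytest.approx(value, abs=1e-10)

    def test_additivity_over_record_lists(self):
        a = [record(["x", "y"], 2.0, {"x": 0.4, "y": 0.1})]
        b = [record(["x"], 4.0, {"x": 0.8})]
        combined = arbitrage_fi(a + b).set_index("marker")["fi"]
        separate_x = (
            arbitrage_fi(a).set_index("marker")["fi"]["x"]
            + arbitrage_fi(b).set_index("marker")["fi"]["x"]
        )
        assert combined["x"] == pytest.approx(separate_x)

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, derandomize=True)
    def test_mae_scale_property(self, c):
        base = [
            record(["x", "y"], 2.0, {"x": 0.4, "y": 0.1}),
            record(["x"], 5.0, {"x": 0.2}),
        ]
        scaled = [
            record(list(r.space.markers), r.mae * c, dict(r.importance)) for r in base
        ]
        fi0 = arbitrage_fi(base).set_index("marker")["fi"]
        fi1 = arbitrage_fi(scaled).set_index("marker")["fi"]
        assert np.allclose(fi1, fi0 / c)

    def test_zero_mae_and_missing_importance_rejected(self):
        with pytest.raises(DegenerateInputError, match="MAE = 0"):
            arbitrage_fi([record(["a"], 0.0, {"a": 0.1})])
        with pytest.raises(DataError, match="lacks an importance"):
            arbitrage_fi([record(["a", "b"], 1.0, {"a": 0.1})])
        with pytest.raises(DataError, match="at least one"):
            arbitrage_fi([])


class TestEnumerateSpaces:
    def test_two_candidates_exhaustive(self, small_cohort):
        spaces = enumerate_feature_spaces(
            small_cohort, ["hemoglobin", "rdw"], n_spaces=3, min_eligible=1, seed=0
        )
        assert {s.markers for s in spaces} == {
            ("hemoglobin",), ("rdw",), ("hemoglobin", "rdw")
        }

    def test_requesting_too_many_states_maximum(self, small_cohort):
        with pytest.raises(DataError, match="maximum attainable is 3"):
            enumerate_feature_spaces(small_cohort, ["hemoglobin", "rdw"], n_spaces=5)

    def test_default_yields_exactly_320(self, small_cohort):
        spaces = enumerate_feature_spaces(small_cohort, seed=0)
        assert len(spaces) == 320
        assert len({s.markers for s in spaces}) == 320
        assert all(s.eligible_n >= 50 for s in spaces)

    def test_no_missingness_eligible_n_is_n(self):
        frame = make_frame(n=300, n_noise_markers=4)
        spaces = enumerate_feature_spaces(
            frame, ["m1", "noise1", "noise2", "noise3"], n_spaces=10, min_eligible=1,
            seed=0,
        )
        assert all(s.eligible_n == 300 for s in spaces)


class TestFitEnsemble:
    def test_noise_marker_importance_near_zero(self):
        """Permutation importance of a pure-noise marker is ~0."""
        frame = make_frame(n=2000, noise=2.0)
        spaces = [make_space(frame, ["m1", "noise1"])]
        records = fit_arbitrage_ensemble(frame, spaces, seed=0)
        assert len(records) == 1
        assert abs(records[0].importance["noise1"]) < 0.05 * records[0].mae + 0.05
        assert records[0].importance["m1"] > 1.0  # strongly age-linked

    def test_matches_sklearn_permutation_importance(self):
        """The batched permutation scorer agrees with sklearn's."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.inspection import permutation_importance as sk_pfi
        from sklearn.model_selection import train_test_split

        from hemoclock.arbitrage import _batched_permutation_mae_increase

        frame = make_frame(n=600, noise=1.0, n_noise_markers=2)
        cols = ["m1", "noise1", "noise2"]
        x_tr, x_te, y_tr, y_te = train_test_split(
            frame[cols].to_numpy(), frame["age"].to_numpy(float), test_size=0.2,
            random_state=0,
        )
        forest = RandomForestRegressor(n_estimators=30, random_state=0).fit(x_tr, y_tr)
        mae = float(np.mean(np.abs(forest.predict(x_te) - y_te)))
        ours = _batched_permutation_mae_increase(
            forest, x_te, y_te, mae, 30, np.random.default_rng(0)
        )
        theirs = sk_pfi(
            forest, x_te, y_te, scoring="neg_mean_absolute_error", n_repeats=30,
            random_state=0,
        ).importances_mean
        # same estimand, different permutation draws: agree within MC error
        assert np.allclose(ours, theirs, atol=0.15, rtol=0.05)
        assert np.argmax(ours) == np.argmax(theirs) == 0

    def test_informative_marker_positive_in_both_spaces(self):
        frame = make_frame(n=1500, noise=1.0, n_noise_markers=2)
        spaces = [make_space(frame, ["m1", "noise1"]), make_space(frame, ["m1", "noise2"])]
        records = fit_arbitrage_ensemble(frame, spaces, seed=1)
        assert all(r.importance["m1"] > 0 for r in records)

    def test_small_space_skipped_with_warning(self):
        small = make_frame(n=30)
        with pytest.warns(UserWarning, match="skipping feature space"):
            records = fit_arbitrage_ensemble(small, [make_space(small, ["m1"])], seed=0)
        assert records == []


class TestSelectFeatureSets:
    def test_no_missingness_prefix_nesting(self):
        frame = make_frame(n=400, noise=1.0, n_noise_markers=3)
        scores = pd.DataFrame(
            {"marker": ["m1", "noise1", "noise2", "noise3"], "fi": [4.0, 3.0, 2.0, 1.0],
             "n_models": [1, 1, 1, 1]}
        )
        sets = select_feature_sets(scores, frame, n_sets=3)
        sizes = [len(s.markers) for s in sets]
        assert sizes == sorted(sizes)
        assert len(sets[-1].markers) == 4  # the maximal set dominates
        for smaller, larger in zip(sets, sets[1:]):
            assert larger.markers[: len(smaller.markers)] == smaller.markers
        assert all(s.eligible_n == 400 for s in sets)

    def test_equal_fi_breaks_ties_by_name(self):
        frame = make_frame(n=100, n_noise_markers=2)
        scores = pd.DataFrame(
            {"marker": ["noise2", "noise1"], "fi": [1.0, 1.0], "n_models": [1, 1]}
        )
        sets = select_feature_sets(scores, frame, n_sets=2)
        assert sets[0].markers == ("noise1",)
        shuffled = select_feature_sets(scores.iloc[::-1], frame, n_sets=2)
        assert [s.markers for s in shuffled] == [s.markers for s in sets]

    def test_nested_fixture_recovers_planted_sizes(self):
        """The full selection stage finds the planted 14/15/18 spaces.

        Runs the default 320-space arbitrage ensemble on the tiered
        fixture; the knee selection must return the three planted
        nested feature spaces exactly (fixed seed; min_eligible raised
        to 150 so micro-spaces do not add importance noise).
        """
        from hemoclock.fixtures import NESTED_SPACES, nested_fixture_cohort

        cohort = nested_fixture_cohort(1500, seed=1)
        spaces = enumerate_feature_spaces(cohort, n_spaces=320, min_eligible=150, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = fit_arbitrage_ensemble(
                cohort, spaces, seed=1, min_eligible=150, n_permutation_repeats=10
            )
        scores = arbitrage_fi(records)
        sets = select_feature_sets(scores, cohort)
        assert [len(s.markers) for s in sets] == [14, 15, 18]
        for selected, planted in zip(sets, NESTED_SPACES):
            assert sorted(selected.markers) == sorted(planted)

    def test_single_age_linked_marker_ranks_first(self):
        """Planted recovery: the only informative marker tops the FI ranking."""
        frame = make_frame(n=2000, noise=1.0, n_noise_markers=4)
        spaces = enumerate_feature_spaces(
            frame, ["m1"] + [f"noise{j}" for j in range(1, 5)], n_spaces=25,
            min_eligible=50, seed=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = fit_arbitrage_ensemble(frame, spaces, n_trees=40, seed=0)
        scores = arbitrage_fi(records)
        assert scores.loc[0, "marker"] == "m1"
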