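"""Age clock: splits, normalization, training contract, metric oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoclock import (
    ConfigError,
    DataError,
    DegenerateInputError,
    SplitSpec,
    normalize_markers,
    predict_age,
    regression_metrics,
    split_train_test,
    train_age_model,
)
from hemoclock.clock import ALL_WITH_SMOKING
from tests.conftest import make_frame


def metrics_oracle(y, yhat, epsilon):
    """Plain-loop reference for r, R^2, MAE and epsilon-accuracy."""
    n = len(y)
    my, myh = sum(y) / n, sum(yhat) / n
    num = sum((a - my) * (b - myh) for a, b in zip(y, yhat))
    dy = math.sqrt(sum((a - my) ** 2 for a in y))
    dyh = math.sqrt(sum((b - myh) ** 2 for b in yhat))
    r = num / (dy * dyh)
    r2 = 1.0 - sum((b - a) ** 2 for a, b in zip(y, yhat)) / sum((a - my) ** 2 for a in y)
    mae = sum(abs(b - a) for a, b in zip(y, yhat)) / n
    acc = sum(1 for a, b in zip(y, yhat) if a - epsilon <= b <= a + epsilon) / n
    return r, r2, mae, acc


def pred_frame(y, yhat):
    return pd.DataFrame(
        {"y_true": y, "y_pred": yhat, "age": y, "sex": 0, "smoking": 0}
    )


class TestSplit:
    def test_80_20_counts_and_reproducibility(self):
        frame = make_frame(n=1000)
        train, test = split_train_test(frame, SplitSpec(seed=9))
        assert (len(train), len(test)) == (800, 200)
        assert set(train.index).isdisjoint(test.index)
        assert len(train) + len(test) == 1000
        train2, _ = split_train_test(frame, SplitSpec(seed=9))
        assert train.index.tolist() == train2.index.tolist()

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ConfigError, match="train_fraction"):
            split_train_test(make_frame(n=100), SplitSpec(train_fraction=1.0))

    def test_stratified_by_decade(self):
        frame = make_frame(n=2000)
        train, test = split_train_test(frame, SplitSpec(seed=0))
        overall = (frame["age"] // 10).value_counts(normalize=True)
        in_test = (test["age"] // 10).value_counts(normalize=True)
        assert (overall - in_test).abs().max() < 0.03


class TestNormalize:
    def test_z_scoring_against_train_statistics(self):
        train = pd.DataFrame({"m": [8.0, 10.0, 12.0]})  # mean 10, SD 2
        target = pd.DataFrame({"m": [14.0]})
        out = normalize_markers(train, target, ["m"])
        assert out.loc[0, "m"] == pytest.approx(2.0)
        self_applied = normalize_markers(train, train, ["m"])
        assert self_applied["m"].mean() == pytest.approx(0.0)
        assert self_applied["m"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_marker_rejected_by_name(self):
        train = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(DegenerateInputError, match="flat"):
            normalize_markers(train, train, ["flat"])


class TestTrainAgeModel:
    def test_contamination_guards(self):
        frame = make_frame(n=200)
        nonsmokers = frame[frame["smoking"] == 0]
        with pytest.raises(ConfigError, match="smoking"):
            train_age_model(nonsmokers, ["m1", "smoking"], SplitSpec())
        with pytest.raises(DataError, match="contains smokers"):
            train_age_model(frame, ["m1"], SplitSpec())

    def test_smoking_feature_allowed_when_configured(self):
        frame = make_frame(n=300, noise=1.0)
        spec = SplitSpec(train_population=ALL_WITH_SMOKING)
        model = train_age_model(frame, ["m1", "smoking"], spec, estimator="linear")
        assert np.isfinite(model.predict(frame)).all()

    def test_noiseless_linear_signal_small_network(self):
        """A clean linear age signal is learned to < 1 year held-out MAE."""
        frame = make_frame(n=2000, seed=1)
        frame["smoking"] = 0
        spec = SplitSpec(seed=1)
        train, test = split_train_test(frame, spec)
        model = train_age_model(train, ["m1", "noise1"], spec, estimator="mlp")
        report = regression_metrics(predict_age(model, test))
        assert report.mae < 1.0

    def test_pure_noise_matches_constant_predictor(self):
        """Without signal the clock degrades to predicting the mean age."""
        frame = make_frame(n=2000, seed=2, slope=0.0, noise=1.0)
        frame["m1"] = np.random.default_rng(2).normal(size=len(frame))
        frame["smoking"] = 0
        spec = SplitSpec(seed=2)
        train, test = split_train_test(frame, spec)
        model = train_age_model(train, ["m1", "noise1"], spec, estimator="gbt")
        report = regression_metrics(predict_age(model, test))
        constant_mae = np.mean(np.abs(test["age"] - train["age"].mean()))
        assert report.mae == pytest.approx(constant_mae, rel=0.10)

    def test_row_permutation_permutes_predictions(self):
        frame = make_frame(n=400, noise=1.0)
        frame["smoking"] = 0
        model = train_age_model(frame, ["m1"], SplitSpec(), estimator="linear")
        base = predict_age(model, frame)["y_pred"].to_numpy()
        perm = np.random.default_rng(0).permutation(len(frame))
        shuffled = predict_age(model, frame.iloc[perm])["y_pred"].to_numpy()
        assert np.array_equal(shuffled, base[perm])

    def test_missing_feature_column_named(self):
        frame = make_frame(n=200, noise=1.0)
        frame["smoking"] = 0
        model = train_age_model(frame, ["m1"], SplitSpec(), estimator="linear")
        with pytest.raises(DataError, match="m1"):
            model.predict(frame.drop(columns=["m1"]))

    def test_test_labels_do_not_leak_into_training(self):
        frame = make_frame(n=500, noise=1.0)
        frame["smoking"] = 0
        spec = SplitSpec(seed=3)
        train, test = split_train_test(frame, spec)
        model = train_age_model(train, ["m1"], spec, estimator="linear")
        before = predict_age(model, test)["y_pred"].to_numpy()
        shuffled_test = test.copy()
        shuffled_test["age"] = np.random.default_rng(1).permutation(test["age"].to_numpy())
        model2 = train_age_model(train, ["m1"], spec, estimator="linear")
        after = predict_age(model2, shuffled_test)["y_pred"].to_numpy()
        assert np.array_equal(before, after)

    def test_save_load_roundtrip(self, tmp_path):
        frame = make_frame(n=200, noise=1.0)
        frame["smoking"] = 0
        model = train_age_model(frame, ["m1"], SplitSpec(), estimator="linear")
        path = tmp_path / "clock.joblib"
        model.save(path)
        from hemoclock import AgePredictor

        loaded = AgePredictor.load(path)
        assert np.array_equal(loaded.predict(frame), model.predict(frame))
        assert (tmp_path / "clock.joblib.json").exists()


class TestRegressionMetrics:
    def test_identity_prediction(self):
        report = regression_metrics(pred_frame([30.0, 50.0, 70.0], [30.0, 50.0, 70.0]))
        assert (report.r, report.r2, report.mae) == (1.0, 1.0, 0.0)
        assert report.epsilon_accuracy == 1.0

    def test_epsilon_boundary_is_inclusive(self):
        """A 5-year miss at epsilon = 5 counts as correct."""
        report = regression_metrics(pred_frame([50.0, 50.0], [55.0, 45.0]), epsilon=5)
        assert report.epsilon_accuracy == 1.0
        assert report.mae == 5.0

    def test_hand_example(self):
        report = regression_metrics(pred_frame([50.0, 60.0], [55.0, 55.0]), epsilon=5)
        assert report.mae == 5.0
        assert report.epsilon_accuracy == 1.0

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            y = rng.uniform(20, 90, n)
            yhat = y + rng.normal(0, 5, n)
            eps = float(rng.uniform(1, 15))
            report = regression_metrics(pred_frame(y, yhat), epsilon=eps)
            r, r2, mae, acc = metrics_oracle(y.tolist(), yhat.tolist(), eps)
            assert report.r == pytest.approx(r, abs=1e-10)
            assert report.r2 == pytest.approx(r2, abs=1e-10)
            assert report.mae == pytest.approx(mae, abs=1e-10)
            assert report.epsilon_accuracy == pytest.approx(acc, abs=1e-10)

    def test_r2_at_most_one_and_one_iff_exact(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(20, 90, 50)
        noisy = regression_metrics(pred_frame(y, y + rng.normal(0, 3, 50)))
        assert noisy.r2 < 1.0
        exact = regression_metrics(pred_frame(y, y))
        assert exact.r2 == 1.0

    @given(st.floats(min_value=0.0, max_value=30.0), st.floats(min_value=0.0, max_value=30.0))
    @settings(max_examples=30, derandomize=True)
    def test_epsilon_accuracy_nondecreasing(self, e1, e2):
        rng = np.random.default_rng(9)
        y = rng.uniform(20, 90, 30)
        yhat = y + rng.normal(0, 8, 30)
        lo, hi = sorted([e1, e2])
        frame = pred_frame(y, yhat)
        assert (
            regression_metrics(frame, epsilon=lo).epsilon_accuracy
            <= regression_metrics(frame, epsilon=hi).epsilon_accuracy
        )

    def test_zero_variance_reports_undefined(self):
        report = regression_metrics(pred_frame([50.0, 50.0], [49.0, 52.0]))
        assert report.r is None and report.r2 is None
        assert report.mae == pytest.approx(1.5)
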