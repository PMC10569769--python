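"""Regression-stage tests: search sampling, CV mechanics, model selection."""

import numpy as np
import pandas as pd
import pytest

from navfair.predictor import (
    FAMILY_ORDER,
    MeanBaseline,
    TuningResult,
    fit_and_score,
    predict_week,
    random_search_cv,
    sample_configs,
    select_model,
)


def _toy_table(n_patients=60, rows_per=4, seed=0, signal=True):
    """Small labelled table in the model-table schema."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        intensity = rng.gamma(2.0, 0.5) if signal else 1.0
        adi = min(100, max(1, int(50 + 20 * np.log(intensity + 0.1))))
        for w in range(rows_per):
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "specialty_id": "gi",
                    "week": w,
                    "age": int(rng.integers(30, 90)),
                    "adi": adi,
                    "rucc": int(rng.integers(1, 10)),
                    "weeks_since_enrollment": w + 1,
                    "util_1wk": 0,
                    "util_4wk": 0,
                    "util_12wk": 0,
                    "util_trend_4wk": 0,
                    "sex": "F",
                    "insurance": "Medicare",
                    "cancer_type": "colorectal",
                    "cluster_id": "0",
                    "target": rng.poisson(intensity if signal else 1.0),
                }
            )
    return pd.DataFrame(rows)


class TestSampleConfigs:
    def test_exhausts_small_finite_space_with_warning(self):
        space = {"max_depth": ("int", 3, 4)}
        with pytest.warns(UserWarning, match="distinct configs"):
            cfgs = sample_configs(space, 15, np.random.default_rng(0))
        assert sorted(c["max_depth"] for c in cfgs) == [3, 4]

    def test_draws_requested_count_and_respects_bounds(self):
        space = {
            "lr": ("loguniform", 0.01, 0.3),
            "depth": ("int", 2, 8),
            "sub": ("uniform", 0.6, 1.0),
        }
        cfgs = sample_configs(space, 15, np.random.default_rng(1))
        assert len(cfgs) == 15
        assert all(0.01 <= c["lr"] <= 0.3 for c in cfgs)
        assert all(2 <= c["depth"] <= 8 for c in cfgs)

    def test_deterministic_for_fixed_seed(self):
        space = {"depth": ("int", 2, 8), "lr": ("loguniform", 0.01, 0.3)}
        a = sample_configs(space, 10, np.random.default_rng(5))
        b = sample_configs(space, 10, np.random.default_rng(5))
        assert a == b


class TestRandomSearch:
    def test_single_config_space_wins(self):
        table = _toy_table()
        space = {"max_depth": ("int", 3, 3), "n_estimators": ("int", 20, 20)}
        with pytest.warns(UserWarning):
            result = random_search_cv(table, search_space=space, n_samples=15, seed=0)
        assert result.best_config == {"max_depth": 3, "n_estimators": 20}

    def test_tie_goes_to_first_sampled(self):
        # constant target -> every config achieves the same CV MSE
        table = _toy_table(signal=False)
        table["target"] = 2
        space = {"max_depth": ("int", 2, 4)}
        with pytest.warns(UserWarning):
            result = random_search_cv(table, search_space=space, n_samples=5, seed=1)
        assert result.best_config == result.configs[0]
        assert len(set(np.round(result.cv_mse, 12))) == 1

    def test_folds_are_patient_grouped(self):
        from sklearn.model_selection import GroupKFold

        table = _toy_table()
        groups = table["patient_id"].to_numpy()
        for tr, va in GroupKFold(n_splits=3).split(table, groups=groups):
            assert not set(groups[tr]) & set(groups[va])

    def test_deterministic(self):
        table = _toy_table()
        space = {"max_depth": ("int", 2, 6), "n_estimators": ("int", 10, 60)}
        a = random_search_cv(table, search_space=space, n_samples=4, seed=3)
        b = random_search_cv(table, search_space=space, n_samples=4, seed=3)
        assert a.best_config == b.best_config and a.cv_mse == b.cv_mse

    def test_tuned_beats_untuned_on_signal_rich_data(self):
        """Tuned CV-MSE <= untuned default's CV-MSE in at least 4/5 seeds."""
        space = {
            "max_depth": ("int", 2, 6),
            "learning_rate": ("loguniform", 0.02, 0.3),
            "n_estimators": ("int", 30, 150),
        }
        wins = 0
        for seed in range(5):
            table = _toy_table(n_patients=120, seed=seed)
            tuned = random_search_cv(table, search_space=space, n_samples=6, seed=seed)
            default = random_search_cv(
                table,
                search_space={"max_depth": ("int", 4, 4)},
                n_samples=1,
                seed=seed,
            )
            wins += tuned.best_cv_mse <= default.best_cv_mse + 1e-12
        assert wins >= 4


class TestFitAndScore:
    def test_constant_target_scores_zero(self):
        train = _toy_table(seed=1)
        test = _toy_table(seed=2)
        train["target"] = 3
        test["target"] = 3
        test["patient_id"] = "q" + test["patient_id"]
        mse = fit_and_score(train, test, config={"n_estimators": 20})
        assert mse == pytest.approx(0.0, abs=1e-6)

    def test_empty_test_rejected(self):
        table = _toy_table()
        with pytest.raises(ValueError):
            fit_and_score(table, table.iloc[0:0])

    def test_overlapping_patients_rejected(self):
        table = _toy_table()
        with pytest.raises(ValueError, match="overlap"):
            fit_and_score(table, table)


class TestSelectModel:
    def _result(self, family, mse):
        return TuningResult(family, [], [], {}, 0.0, 0, test_mse=mse)

    def test_published_mse_ordering(self):
        results = [
            self._result("gradient_boosted_trees", 0.103),
            self._result("random_forest", 0.114),
            self._result("neural_network", 0.129),
        ]
        assert select_model(results) == "gradient_boosted_trees"

    def test_single_result(self):
        assert select_model([self._result("random_forest", 1.0)]) == "random_forest"

    def test_tie_breaks_by_family_order(self):
        results = [
            self._result("neural_network", 0.2),
            self._result("gradient_boosted_trees", 0.2),
        ]
        assert select_model(results) == "gradient_boosted_trees"
        assert FAMILY_ORDER.index("gradient_boosted_trees") == 0


class TestPredictWeek:
    def test_mean_baseline_predicts_training_mean(self):
        base = MeanBaseline().fit(None, np.array([0.0, 1.0, 2.0]))
        out = predict_week(base, _toy_table(n_patients=3, rows_per=1))
        assert np.allclose(out, 1.0)

    def test_unfitted_baseline_rejected(self):
        with pytest.raises(ValueError):
            predict_week(MeanBaseline(), _toy_table(n_patients=2, rows_per=1))

    def test_predictions_finite_and_nonnegative(self):
        table = _toy_table(n_patients=80)
        from navfair.predictor import make_model, _feature_frame

        model = make_model("gradient_boosted_trees", {"n_estimators": 30}, seed=0)
        model.fit(_feature_frame(table), table["target"].to_numpy(float))
        out = predict_week(model, table)
        assert np.isfinite(out).all() and (out >= 0).all()
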