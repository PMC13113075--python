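import dataclasses

import numpy as np
import pandas as pd
import pytest

from vocpartition import FeatureTable, default_config, generate_dataset
from vocpartition import subject_cv as scv
from vocpartition.evaluation import null_config

from conftest import make_rows


@pytest.fixture(scope="module")
def table():
    return generate_dataset(default_config(seed=77))


@pytest.fixture(scope="module")
def plan(table):
    return scv.make_grouped_folds(table, k=5, seed=7)


@pytest.fixture(scope="module")
def logit_cv(table, plan):
    return scv.run_cv(table, plan, models=("logit",), seed=7)["logit"]


class TestFoldPlans:
    def test_balanced_disjoint_folds(self, table, plan):
        sizes = pd.Series(plan.assignments).value_counts()
        assert sorted(sizes) == [8] * 5
        for f in range(5):
            test_animals = set(plan.animals_in_fold(f))
            train_animals = set(plan.assignments) - test_animals
            assert not test_animals & train_animals

    def test_leave_one_animal_out(self, table):
        plan = scv.make_grouped_folds(table, k=40, seed=0)
        assert sorted(pd.Series(plan.assignments).value_counts()) == [1] * 40

    def test_k_exceeding_animals_rejected(self, table):
        with pytest.raises(ValueError, match="exceeds"):
            scv.make_grouped_folds(table, k=41)

    def test_stratified_beats_random_on_class_balance(self):
        # skewed data: availability makes class frequencies phase-dependent
        cfg = default_config(seed=15)
        table = generate_dataset(cfg)

        def max_deviation(plan):
            df = table.data
            global_frac = df["condition"].value_counts(normalize=True)
            worst = 0.0
            for f in range(plan.k):
                sub = df[df["animal_id"].isin(plan.animals_in_fold(f))]
                frac = sub["condition"].value_counts(normalize=True)
                worst = max(worst, (frac - global_frac).abs().max())
            return worst

        strat = [max_deviation(scv.make_grouped_folds(table, 5, seed=s))
                 for s in range(5)]
        rand = [max_deviation(scv.make_grouped_folds(table, 5, seed=s,
                                                     stratify_by=None))
                for s in range(5)]
        assert np.median(strat) <= np.median(rand)

    def test_determinism(self, table):
        a = scv.make_grouped_folds(table, 5, seed=3)
        b = scv.make_grouped_folds(table, 5, seed=3)
        assert a.assignments == b.assignments


class TestFitFold:
    def test_shared_animals_rejected(self, table):
        df = table.data
        with pytest.raises(scv.LeakageError):
            scv.fit_fold(df, df, model="logit")

    def test_imputation_uses_train_median_not_test(self):
        cfg = default_config(seed=20)
        table = generate_dataset(cfg)
        df = table.data
        animals = sorted(df["animal_id"].unique())
        train = df[df["animal_id"].isin(animals[:30])].copy()
        test = df[df["animal_id"].isin(animals[30:])].copy()
        # shift the test-fold pitch distribution far away: if the imputer
        # leaked test statistics, imputed values would follow the shift
        test["pitch"] = test["pitch"] + 5000.0
        _, _, pipe = scv.fit_fold(train, test, model="logit", seed=0)
        imputer = pipe.named_steps["prep"].named_transformers_["num"].named_steps["impute"]
        num_cols, _ = scv._feature_columns("full")
        pitch_stat = imputer.statistics_[num_cols.index("pitch")]
        assert pitch_stat == pytest.approx(train["pitch"].median())
        assert abs(pitch_stat - test["pitch"].median()) > 1000

    def test_constant_feature_dropped_with_warning(self):
        df = make_rows(n_animals=8, n_recordings=3)
        df["condition"] = np.where(df["animal_id"].astype(int) % 2 == 0,
                                   "normal", "pain")
        df["intensity"] = 70.0 + 10.0 * (df["condition"] == "pain")
        train = df[df["animal_id"] <= "04"]
        test = df[df["animal_id"] > "04"]
        with pytest.warns(UserWarning, match="zero-variance"):
            pred, proba, _ = scv.fit_fold(train, test, model="logit", seed=0)
        assert proba.shape == (len(test), 6)

    def test_separable_classes_high_recall(self):
        cfg = default_config(seed=25)
        for tp in cfg.traits.values():
            tp.sigma2_animal = 0.0
            tp.sigma2_recording = 0.0
        # widen condition separations on intensity massively
        cfg.traits["intensity"].condition = {
            "pain": 40.0, "hunger": 80.0, "thirst": 120.0, "cold": 160.0,
            "heat": 200.0}
        cfg.traits["intensity"].sigma2_resid = 1.0
        table = generate_dataset(cfg)
        plan = scv.make_grouped_folds(table, k=5, seed=1)
        res = scv.run_cv(table, plan, models=("rf",), seed=1,
                         model_params={"rf": {"n_estimators": 100}})["rf"]
        assert res.balanced_accuracy > 0.95

    def test_missing_class_in_train_errors(self):
        df = make_rows(n_animals=6, n_recordings=2)
        df.loc[df["animal_id"] == "01", "condition"] = "pain"
        train = df[df["animal_id"] != "01"]
        test = df[df["animal_id"] == "01"]
        with pytest.raises(ValueError, match="absent from the training fold"):
            scv.fit_fold(train, test, model="logit")


class TestMetrics:
    def test_perfect_predictions(self):
        y = ["pain", "cold", "heat"] * 4
        m = scv.metrics(y, y)
        assert m["balanced_accuracy"] == 1.0
        assert m["macro_f1"] == 1.0

    def test_hand_computed_confusion(self):
        # confusion [[8,2],[4,6]] -> recalls 0.8, 0.6 -> BA 0.7
        y_true = ["normal"] * 10 + ["pain"] * 10
        y_pred = ["normal"] * 8 + ["pain"] * 2 + ["normal"] * 4 + ["pain"] * 6
        m = scv.metrics(y_true, y_pred)
        assert m["balanced_accuracy"] == pytest.approx(0.7)

    def test_all_one_class_predictor_on_balanced_classes(self):
        labels = list(scv.CONDITION_LEVELS)
        y_true = labels * 10
        y_pred = ["pain"] * 60
        m = scv.metrics(y_true, y_pred)
        assert m["balanced_accuracy"] == pytest.approx(1 / 6)

    def test_agrees_with_sklearn(self, logit_cv):
        from sklearn.metrics import balanced_accuracy_score, f1_score
        assert logit_cv.balanced_accuracy == pytest.approx(
            balanced_accuracy_score(logit_cv.y_true, logit_cv.y_pred))
        assert logit_cv.macro_f1 == pytest.approx(
            f1_score(logit_cv.y_true, logit_cv.y_pred, average="macro"))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            scv.metrics(["pain"], ["sleepy"])


class TestRunCV:
    def test_probabilities_and_pooling_invariants(self, logit_cv):
        assert np.allclose(logit_cv.proba.sum(axis=1), 1.0, atol=1e-9)
        assert (logit_cv.fold_of_row >= 0).all()
        # confusion marginals match per-class supports
        assert (logit_cv.confusion_raw.sum(axis=1).to_numpy()
                == logit_cv.per_class["support"].to_numpy()).all()
        # rows of the normalized confusion sum to 1 for supported classes
        sums = logit_cv.confusion_row_norm.sum(axis=1)
        supported = logit_cv.per_class["support"] > 0
        assert np.allclose(sums[supported], 1.0)

    def test_determinism(self, table, plan):
        a = scv.run_cv(table, plan, models=("rf",), seed=5,
                       model_params={"rf": {"n_estimators": 50}})["rf"]
        b = scv.run_cv(table, plan, models=("rf",), seed=5,
                       model_params={"rf": {"n_estimators": 50}})["rf"]
        assert (a.y_pred == b.y_pred).all()
        assert a.macro_f1 == b.macro_f1

    def test_complete_case_drops_missing_pitch_rows(self, table, plan):
        res = scv.run_cv(table, plan, models=("logit",), missing="complete-case",
                         seed=7)["logit"]
        assert len(res.y_true) == table.data["pitch"].notna().sum()

    def test_pitch_excluded_not_better_than_full(self, table, plan):
        # pitch is informative in the generator, so removing it should not
        # improve the fit (sensitivity direction)
        full = scv.run_cv(table, plan, models=("logit",), seed=7)["logit"]
        nopitch = scv.run_cv(table, plan, models=("logit",),
                             feature_spec="nopitch", seed=7)["logit"]
        assert nopitch.macro_f1 <= full.macro_f1 + 0.02

    def test_unknown_model_and_spec_rejected(self, table, plan):
        with pytest.raises(ValueError, match="unknown model"):
            scv.run_cv(table, plan, models=("svm",))
        with pytest.raises(ValueError, match="feature spec"):
            scv.run_cv(table, plan, models=("logit",), feature_spec="everything")
        with pytest.raises(ValueError, match="missing-data"):
            scv.run_cv(table, plan, models=("logit",), missing="drop")
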