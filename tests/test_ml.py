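"""Boosted survival ladder, evaluation metrics, TreeSHAP attribution."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from actirisk.ml import (
    ModelLadderSpec,
    brier_score,
    evaluate,
    explain,
    fit_ladder,
    net_benefit,
)
from actirisk.simulate import EffectConfig, SimConfig, simulate_cohort


@pytest.fixture(scope="module")
def signal_cohort():
    cfg = SimConfig(n_participants=8000, seed=81, event_target=400)
    cohort, _, truth = simulate_cohort(cfg, with_activity=False)
    return cohort, truth


@pytest.fixture(scope="module")
def fitted(signal_cohort):
    cohort, _ = signal_cohort
    return fit_ladder(cohort, ModelLadderSpec(seed=7, max_rounds=200))


class TestFitLadder:
    def test_nested_feature_sets(self, fitted):
        fs = fitted.feature_sets
        assert set(fs["baseline"]) < set(fs["plus_prs"]) <= set(fs["full"])
        assert set(fs["baseline"]) < set(fs["plus_rar"]) <= set(fs["full"])

    def test_split_is_partition(self, fitted, signal_cohort):
        cohort, _ = signal_cohort
        joint = np.concatenate([fitted.train_index, fitted.valid_index])
        assert len(joint) == len(cohort)
        assert len(np.unique(joint)) == len(cohort)

    def test_refuses_underpowered_training_split(self):
        cfg = SimConfig(n_participants=2000, seed=83, event_target=20)
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        with pytest.raises(ValueError, match="events"):
            fit_ladder(cohort, ModelLadderSpec(seed=1))

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(5)
        n = 6000
        event = rng.binomial(1, 0.08, n)
        # administrative censoring at 10 y; events at uniform times before
        cohort = pd.DataFrame({
            "follow_up": np.where(event == 1, rng.uniform(0.5, 10.0, n), 10.0),
            "event": event,
            "age": rng.normal(56, 8, n),
            "sex_male": rng.binomial(1, 0.44, n),
            "bmi": rng.normal(27, 4, n),
            "townsend": rng.normal(-1.8, 2.7, n),
            "prs": rng.standard_normal(n),
            "amplitude": rng.gamma(9, 5, n),
        })
        ladder = fit_ladder(cohort, ModelLadderSpec(seed=2, max_rounds=100))
        report = evaluate(ladder, cohort)
        assert report.auc["full"] == pytest.approx(0.5, abs=0.07)


class TestEvaluate:
    def test_informative_models_beat_chance(self, fitted, signal_cohort):
        cohort, _ = signal_cohort
        report = evaluate(fitted, cohort)
        assert report.auc["full"] > 0.65
        assert 0 <= report.brier["full"] <= 0.25

    def test_brier_of_prevalence_predictor_closed_form(self):
        rng = np.random.default_rng(11)
        p = 0.05
        y = rng.binomial(1, p, 200000)
        assert brier_score(y, np.full_like(y, p, dtype=float)) == pytest.approx(
            p * (1 - p), rel=0.02
        )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.binomial(1, 0.3, 2000)
        s = rng.standard_normal(2000) + y
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(2 * s)), abs=1e-12
        )

    def test_net_benefit_conventions(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        nb = net_benefit(y, p, np.array([0.05, 0.15]))
        # perfect separation below the split point: NB = prevalence
        assert nb["net_benefit"].iloc[1] == pytest.approx(0.2)
        assert (nb["treat_none"] == 0).all()

    def test_perfect_score_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc_score(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_calibration_deciles_partition_validation(self, fitted, signal_cohort):
        cohort, _ = signal_cohort
        report = evaluate(fitted, cohort)
        tab = report.calibration["full"]
        va_usable = tab["n"].sum()
        assert va_usable > 0.9 * len(fitted.valid_index)


class TestExplain:
    def test_local_accuracy(self, fitted, signal_cohort):
        import xgboost as xgb

        cohort, _ = signal_cohort
        shap = explain(fitted, cohort, "full")
        df = cohort.copy()
        df["smoking_former"] = (df["smoking"] == "former").astype(int)
        df["smoking_current"] = (df["smoking"] == "current").astype(int)
        feats = fitted.feature_sets["full"]
        dm = xgb.DMatrix(df.iloc[fitted.valid_index][feats], feature_names=feats)
        bst = fitted.boosters["full"]
        it = (0, bst.best_iteration + 1)
        margin = bst.predict(dm, iteration_range=it, output_margin=True)
        recon = shap.values.sum(axis=1) + shap.base_value
        assert recon == pytest.approx(margin, abs=1e-4)

    def test_age_and_sex_dominate_importance(self, fitted, signal_cohort):
        cohort, _ = signal_cohort
        shap = explain(fitted, cohort, "full")
        top5 = set(shap.top_features(5).index)
        assert {"age", "sex_male"} & top5

    def test_protective_feature_sign(self, fitted, signal_cohort):
        # higher amplitude was generated protective: attributions anticorrelate
        cohort, _ = signal_cohort
        shap = explain(fitted, cohort, "full")
        j = shap.feature_names.index("amplitude")
        amp = cohort["amplitude"].to_numpy()[fitted.valid_index]
        r = np.corrcoef(amp, shap.values[:, j])[0, 1]
        assert r < -0.2

    def test_duplicated_feature_splits_attribution(self, signal_cohort):
        cohort, _ = signal_cohort
        dup = cohort.copy()
        dup["amplitude_copy"] = dup["amplitude"]
        from actirisk import ml

        spec = ModelLadderSpec(seed=7, max_rounds=100)
        old = ml.BASELINE_FEATURES
        try:
            ml.BASELINE_FEATURES = old + ["amplitude_copy"]
            ladder = fit_ladder(dup, spec)
        finally:
            ml.BASELINE_FEATURES = old
        shap = explain(ladder, dup, "full")
        j1 = shap.feature_names.index("amplitude")
        j2 = shap.feature_names.index("amplitude_copy")
        total = shap.mean_abs["amplitude"] + shap.mean_abs["amplitude_copy"]
        # both duplicates receive a share of the attribution mass
        assert shap.mean_abs["amplitude_copy"] > 0.05 * total
        assert shap.mean_abs["amplitude"] > 0.05 * total
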