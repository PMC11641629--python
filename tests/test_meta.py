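import numpy as np
import pandas as pd
import pytest

from _oracles import roc_auc_oracle
from molue.io import MoleculeEntry, assign_folds
from molue.meta import (
    EvaluationReport,
    MetaClassifier,
    assemble_features,
    binned_diagnostics,
    build_features_crossval,
    crossval_predictions,
    evaluate,
    fit_gradient_boosting,
    fit_logistic,
    roc_auc,
)


def make_ue_frame(n=20, k=5, seed=0, with_mcs=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "smiles": [f"mol{i}" for i in range(n)],
        "y_true": rng.uniform(500, 1500, n),
        "y_ens": rng.uniform(500, 1500, n),
        "abs_error": rng.exponential(20, n),
        "n_cl": rng.integers(0, k, n),
        "mae_cl": rng.uniform(10, 60, n),
        "mdae_cl": rng.uniform(5, 30, n),
        "d_cl": rng.uniform(0, 3, n),
        "s_max_t": rng.uniform(0, 1, n),
        "s_max_c": rng.uniform(0, 1, n),
        "s_max_e": rng.uniform(0, 4, n),
        "m_s1": rng.uniform(0, 50, n),
        "m_s2": rng.uniform(0, 60, n),
        "m_m": rng.uniform(0, 120, n),
    })
    if with_mcs:
        df["s_max_mcs"] = rng.uniform(0, 1, n)
    return df


class TestAssembleFeatures:
    def test_logistic_mode_has_six_columns(self):
        X = assemble_features(make_ue_frame(), "logistic")
        assert X.shape[1] == 6

    def test_ensemble_prediction_scaled_by_1000(self):
        ue = make_ue_frame()
        ue.loc[0, "y_ens"] = 2000.0
        X = assemble_features(ue, "logistic")
        assert X.loc[0, "y_ens_over_1000"] == pytest.approx(2.0)

    def test_full_mode_column_count(self):
        # 9 base features (no MCS) + 20 one-hot clusters + y_ens
        X = assemble_features(make_ue_frame(), "full", k=20)
        assert X.shape[1] == 9 + 20 + 1
        X = assemble_features(make_ue_frame(with_mcs=True), "full", k=20)
        assert X.shape[1] == 10 + 20 + 1

    def test_missing_feature_named(self):
        ue = make_ue_frame().drop(columns=["m_s1"])
        with pytest.raises(ValueError, match="m_s1"):
            assemble_features(ue, "logistic")


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        n = 1000
        labels = np.zeros(n, int)
        labels[:300] = 1
        clf = fit_logistic(pd.DataFrame(index=range(n)), labels)
        assert clf.intercept == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_noise_feature_not_significant(self):
        rng = np.random.default_rng(11)
        n = 10_000
        X = pd.DataFrame({"noise": rng.normal(size=n)})
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        clf = fit_logistic(X, labels)
        assert abs(clf.coef[0]) < 3 * clf.stderr[0]

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        n = 20_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 2.0 * x)))
        labels = (rng.uniform(size=n) < p).astype(int)
        clf = fit_logistic(pd.DataFrame({"x": x}), labels)
        assert abs(clf.intercept - (-1.0)) < 3 * clf.intercept_se
        assert abs(clf.coef[0] - 2.0) < 3 * clf.stderr[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])

    def test_perfect_separation_rejected(self):
        x = np.concatenate([np.zeros(60), np.ones(60)])
        labels = (x > 0.5).astype(int)
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": x}), labels)

    def test_standard_errors_positive(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=500)})
        labels = (rng.uniform(size=500) < 0.4).astype(int)
        clf = fit_logistic(X, labels)
        assert clf.intercept_se > 0 and np.all(clf.stderr > 0)

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        labels = (rng.uniform(size=300) < 0.3).astype(int)
        clf = fit_logistic(X, labels)
        clf.to_json(tmp_path / "m.json")
        back = MetaClassifier.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X))


class TestFitGradientBoosting:
    def test_informative_feature_dominates_gain(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        labels = (x + 0.2 * rng.normal(size=n) > 0.5).astype(int)
        X = pd.DataFrame({
            "signal": x, "c1": np.zeros(n), "c2": np.ones(n),
            "c3": np.full(n, 2.0),
        })
        clf = fit_gradient_boosting(X, labels, seed=0)
        total = sum(clf.gain_importance.values())
        assert clf.gain_importance["signal"] / total > 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=400), "z": rng.normal(size=400)})
        labels = (rng.uniform(size=400) < 0.3).astype(int)
        c1 = fit_gradient_boosting(X, labels, seed=7)
        c2 = fit_gradient_boosting(X, labels, seed=7)
        assert c1.gain_importance == c2.gain_importance

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(size=300)})
        labels = (rng.uniform(size=300) < 0.3).astype(int)
        probs = fit_gradient_boosting(X, labels, seed=0).predict_proba(X)
        assert np.all((probs > 0) & (probs < 1))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_case_three_of_four_concordant(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        scores = rng.normal(size=60)
        scores[rng.integers(0, 60, 10)] = 0.0  # inject ties
        labels = (rng.uniform(size=60) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_oracle(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=80)
        labels = (rng.uniform(size=80) < 0.3).astype(int)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(scores * 2), labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestEvaluate:
    def test_perfect_classifier(self):
        rep = evaluate([0.9, 0.95, 0.01, 0.02], [1, 1, 0, 0], 0.5)
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_threshold_above_all_probabilities(self):
        rep = evaluate([0.01, 0.02, 0.05], [1, 0, 0], 0.5)
        assert rep.tp == rep.fp == 0
        assert rep.precision == 0.0

    def test_metrics_consistent_with_counts(self, rng):
        probs = rng.uniform(size=200)
        labels = (rng.uniform(size=200) < 0.25).astype(int)
        rep = evaluate(probs, labels, 0.15)
        again = EvaluationReport.from_counts(rep.tp, rep.tn, rep.fp, rep.fn)
        assert (rep.f1, rep.precision, rep.recall, rep.accuracy) == (
            again.f1, again.precision, again.recall, again.accuracy)
        assert rep.n == 200

    def test_flag_rule_is_greater_or_equal(self):
        rep = evaluate([0.15, 0.1499], [1, 1], 0.15)
        assert rep.tp == 1 and rep.fn == 1


class TestBinnedDiagnostics:
    def test_constant_feature_single_bin(self):
        out = binned_diagnostics(np.ones(30), np.arange(30.0),
                                 np.zeros(30, int), n_bins=5)
        assert out["count"].tolist() == [30]

    def test_counts_sum_to_n(self, rng):
        out = binned_diagnostics(rng.uniform(size=100),
                                 rng.exponential(size=100),
                                 rng.integers(0, 2, 100), n_bins=8)
        assert out["count"].sum() == 100
        assert len(out) == 8

    def test_monotone_error_structure_recovered(self, rng):
        x = rng.uniform(0, 1, size=2000)
        errors = 10 * x + rng.normal(0, 0.2, size=2000)
        out = binned_diagnostics(x, errors, (errors > 7).astype(int), n_bins=5)
        mae = out["mae"].to_numpy()
        assert np.all(np.diff(mae) > 0)


class _ConstantRegressor:
    """Deterministic base model: predicts heavy-atom count * 100."""

    def fit(self, train_entries, seed):
        return seed  # model is just its seed; predictions ignore training

    def predict(self, model, smiles):
        from rdkit import Chem

        return np.array([
            100.0 * Chem.MolFromSmiles(s).GetNumAtoms() + (model % 7)
            for s in smiles
        ])


class TestCrossvalPipeline:
    SMILES = ["CCO", "CCC", "CCN", "CCCC", "CCOC", "CCS", "CCCl", "CCBr",
              "CCCO", "CCCN", "c1ccccc1", "Cc1ccccc1"]

    def entries(self):
        return [MoleculeEntry(s, 100.0 * (i + 3)) for i, s in
                enumerate(self.SMILES)]

    def test_every_molecule_predicted_once(self):
        out = crossval_predictions(self.entries(), _ConstantRegressor(),
                                   n_folds=3, m_models=2, seed=0)
        assert sorted(e.smiles for e in out) == sorted(self.SMILES)
        assert all(len(e.model_preds) == 2 for e in out)

    def test_deterministic(self):
        a = crossval_predictions(self.entries(), _ConstantRegressor(),
                                 n_folds=3, m_models=2, seed=1)
        b = crossval_predictions(self.entries(), _ConstantRegressor(),
                                 n_folds=3, m_models=2, seed=1)
        assert a == b

    def test_duplicates_never_straddle_folds(self):
        entries = self.entries() + [MoleculeEntry("CCO", 300.0)]
        folded = assign_folds(entries, 3, seed=2)
        cco = {e.fold_id for e in folded if e.smiles == "CCO"}
        assert len(cco) == 1

    def test_feature_table_is_out_of_fold_and_complete(self):
        filled = crossval_predictions(self.entries(), _ConstantRegressor(),
                                      n_folds=3, m_models=2, seed=0)
        ue = build_features_crossval(filled, n_folds=3, seed=0, k=3)
        assert len(ue) == len(self.SMILES)
        required = {"mae_cl", "mdae_cl", "d_cl", "s_max_t", "s_max_c",
                    "s_max_e", "m_s1", "m_s2", "m_m", "y_ens", "n_cl"}
        assert required <= set(ue.columns)
        assert ue.notna().all().all()
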