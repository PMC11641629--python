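import numpy as np
import pytest

from molue.ensemble import fit_error_distribution, label_predictions, compute_threshold
from molue.io import MoleculeEntry, filter_supported
from molue.meta import crossval_pipeline, roc_auc
from molue.synth import (
    SimulationConfig,
    chemical_difficulty,
    generate_molecule_library,
    library_capacity,
    make_prediction_table,
    simulate_ensemble,
    simulate_true_property,
    toy_base_regressor,
)


class TestLibrary:
    def test_unique_valid_and_supported(self):
        smiles = generate_molecule_library(50, seed=1)
        assert len(set(smiles)) == 50
        entries = [MoleculeEntry(s, 1.0) for s in smiles]
        kept, rejected = filter_supported(entries)
        assert not rejected

    def test_deterministic(self):
        assert (generate_molecule_library(30, seed=9)
                == generate_molecule_library(30, seed=9))

    def test_capacity_error(self):
        cap = library_capacity()
        with pytest.raises(ValueError, match=str(cap)):
            generate_molecule_library(cap + 1, seed=0)

    def test_canonical_form(self):
        from molue.io import standardize_smiles

        for s in generate_molecule_library(20, seed=2):
            assert standardize_smiles(s) == s


class TestTrueProperty:
    def test_small_molecules_get_smaller_values(self):
        y = simulate_true_property(["C", "CCCCCCCCCC"], seed=0)
        assert y[0] < y[1]

    def test_deterministic_and_positive(self):
        smiles = generate_molecule_library(40, seed=3)
        y1 = simulate_true_property(smiles, seed=4)
        y2 = simulate_true_property(smiles, seed=4)
        np.testing.assert_array_equal(y1, y2)
        assert np.all(y1 > 0) and np.all(np.isfinite(y1))


class TestSimulateEnsemble:
    def test_zero_scale_gives_exact_predictions(self):
        y = np.array([100.0, 200.0, 300.0])
        cfg = SimulationConfig(n_molecules=3, m_models=4, seed=0, s0=0.0)
        preds, _ = simulate_ensemble(y, cfg)
        np.testing.assert_array_equal(preds, np.tile(y[:, None], (1, 4)))

    def test_independent_noise_averages_out_with_ensemble_size(self):
        y = np.full(4000, 1000.0)
        errs = {}
        for m in (2, 8, 32):
            cfg = SimulationConfig(n_molecules=4000, m_models=m, seed=1,
                                   s0=20.0, gamma=0.0, kappa=0.0)
            preds, _ = simulate_ensemble(y, cfg)
            errs[m] = np.abs(preds.mean(axis=1) - y).mean()
        assert errs[2] > errs[8] > errs[32]
        # averaging m independent errors shrinks them ~ 1/sqrt(m)
        assert errs[2] / errs[32] == pytest.approx(4.0, rel=0.25)

    def test_difficulty_drives_error_magnitude(self):
        y = np.full(4000, 1000.0)
        cfg = SimulationConfig(n_molecules=4000, m_models=4, seed=2,
                               s0=20.0, gamma=2.0, kappa=0.3)
        preds, u = simulate_ensemble(y, cfg)
        abs_err = np.abs(preds.mean(axis=1) - y)
        hard = abs_err[u > 0.75].mean()
        easy = abs_err[u < 0.25].mean()
        assert hard > 2.0 * easy

    def test_correlated_bias_limits_averaging(self):
        y = np.full(4000, 1000.0)
        errs = {}
        for m in (2, 32):
            cfg = SimulationConfig(n_molecules=4000, m_models=m, seed=3,
                                   s0=20.0, gamma=0.0, kappa=1.0)
            preds, _ = simulate_ensemble(y, cfg)
            errs[m] = np.abs(preds.mean(axis=1) - y).mean()
        # the shared bias does not shrink with ensemble size
        assert errs[32] == pytest.approx(errs[2], rel=0.1)

    def test_laplace_abs_errors_look_exponential(self):
        y = np.full(5000, 1000.0)
        cfg = SimulationConfig(n_molecules=5000, m_models=4, seed=4,
                               s0=25.0, gamma=1.0)
        preds, _ = simulate_ensemble(y, cfg)
        abs_err = np.abs(preds.mean(axis=1) - y)
        exp_fit = fit_error_distribution(abs_err, "exponential")
        norm_fit = fit_error_distribution(abs_err, "normal")
        assert exp_fit.log_likelihood > norm_fit.log_likelihood

    def test_spread_auc_needs_difficulty_heterogeneity(self):
        y = np.full(5000, 1000.0)
        aucs = {}
        for gamma in (0.0, 2.0):
            cfg = SimulationConfig(n_molecules=5000, m_models=4, seed=5,
                                   s0=20.0, gamma=gamma, kappa=0.0)
            preds, _ = simulate_ensemble(y, cfg)
            abs_err = np.abs(preds.mean(axis=1) - y)
            m_s1 = np.abs(preds - preds.mean(axis=1, keepdims=True)).mean(axis=1)
            labels = label_predictions(abs_err, compute_threshold(abs_err, 0.85))
            aucs[gamma] = roc_auc(m_s1, labels)
        assert aucs[2.0] > 0.65
        assert aucs[2.0] > aucs[0.0]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(m_models=1)
        with pytest.raises(ValueError):
            SimulationConfig(kappa=1.5)


class TestChemicalDifficulty:
    def test_uniform_margin(self):
        smiles = generate_molecule_library(80, seed=6)
        u = chemical_difficulty(smiles, mix=0.7, seed=0)
        assert u.min() > 0 and u.max() < 1
        assert np.unique(u).size == 80  # a strict ranking

    def test_pure_noise_mix(self):
        smiles = generate_molecule_library(30, seed=7)
        u1 = chemical_difficulty(smiles, mix=0.0, seed=1)
        u2 = chemical_difficulty(smiles, mix=0.0, seed=2)
        assert not np.array_equal(u1, u2)


class TestToyRegressor:
    def test_exact_on_training_molecule(self):
        smiles = generate_molecule_library(30, seed=8)
        y = simulate_true_property(smiles, seed=8)
        entries = [MoleculeEntry(s, float(v)) for s, v in zip(smiles, y)]
        reg = toy_base_regressor()
        reg.drop_fraction = 0.0  # keep every molecule
        model = reg.fit(entries, seed=0)
        preds = reg.predict(model, smiles[:5])
        np.testing.assert_allclose(preds, y[:5])

    def test_bootstrap_replicas_differ(self):
        smiles = generate_molecule_library(60, seed=9)
        y = simulate_true_property(smiles, seed=9)
        train = [MoleculeEntry(s, float(v)) for s, v in
                 zip(smiles[:50], y[:50])]
        reg = toy_base_regressor()
        m1 = reg.fit(train, seed=1)
        m2 = reg.fit(train, seed=2)
        p1 = reg.predict(m1, smiles[50:])
        p2 = reg.predict(m2, smiles[50:])
        assert not np.array_equal(p1, p2)

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            toy_base_regressor().fit([], seed=0)

    def test_pipeline_smoke(self):
        smiles = generate_molecule_library(60, seed=10)
        y = simulate_true_property(smiles, seed=10)
        entries = [MoleculeEntry(s, float(v)) for s, v in zip(smiles, y)]
        filled, ue = crossval_pipeline(entries, toy_base_regressor(),
                                       n_folds=3, m_models=2, seed=0, k=5)
        assert len(filled) == len(ue) == 60
        assert ue.notna().all().all()


class TestMakePredictionTable:
    def test_chemistry_coupling_links_difficulty_to_rarity(self):
        cfg = SimulationConfig(n_molecules=150, seed=11)
        _, u_coupled = make_prediction_table(cfg, couple_chemistry=True)
        entries, _ = make_prediction_table(cfg, couple_chemistry=False)
        assert len(entries) == 150
        assert u_coupled.shape == (150,)
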