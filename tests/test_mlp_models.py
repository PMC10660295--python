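"""The regressors: RAdam/MLP mechanics, the train/predict contract, exact
prediction symmetry, serialization, and grid tuning."""

import numpy as np
import pytest

from pairsyn.evaluation import pcc
from pairsyn.features import PAIR_WIDTH, featurize_pair, swap_pair_vector
from pairsyn.mlp import NumpyMLP, _RAdam
from pairsyn.models import (
    MLPConfig,
    RFConfig,
    GBXConfig,
    default_config,
    load_model,
    predict_pair,
    save_model,
    train_regressor,
)


def _toy_rows(n=64, d=PAIR_WIDTH, seed=0, target="linear"):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, d)) < 0.05).astype(np.float32)
    if target == "linear":
        w = rng.standard_normal(d) * (rng.random(d) < 0.02)
        y = X @ w
    else:
        y = np.full(n, 0.7)
    return X, y.astype(np.float64)


class TestRAdamUpdate:
    def test_first_step_is_unrectified_momentum_step(self):
        """For t=1, rho_1 < 4, so the update must be lr * m_hat = lr * g."""
        opt = _RAdam(lr=0.1)
        p = np.array([1.0])
        g = np.array([2.0])
        opt.step([p], [g])
        # m_hat = g exactly at t=1; rectification off => p -= lr * g
        assert p[0] == pytest.approx(1.0 - 0.1 * 2.0, abs=1e-12)

    def test_late_steps_use_rectified_adaptive_scale(self):
        opt = _RAdam(lr=0.1)
        p = np.array([0.0])
        for t in range(10):
            opt.step([p], [np.array([1.0])])
        # constant gradient: v_hat -> 1, so steps approach lr * r_t < lr
        assert opt.t == 10
        rho_inf = 2 / (1 - opt.beta2) - 1
        rho_t = rho_inf - 2 * 10 * opt.beta2**10 / (1 - opt.beta2**10)
        assert rho_t > 4  # rectified branch active by t=10


class TestNumpyMLP:
    def test_training_loss_decreases(self):
        X, y = _toy_rows(128, seed=1)
        net = NumpyMLP(X.shape[1], hidden_width=32, seed=0)
        net.fit(X, y, epochs=20, batch_size=32)
        assert net.loss_history[-1] < net.loss_history[0]

    def test_constant_target_learned_to_tolerance(self):
        X, y = _toy_rows(64, seed=2, target="constant")
        net = NumpyMLP(X.shape[1], hidden_width=16, seed=0)
        net.fit(X, y, epochs=300, batch_size=64, learning_rate=3e-3)
        assert np.allclose(net.predict(X), 0.7, atol=1e-3)

    def test_same_seed_same_weights_hash(self):
        X, y = _toy_rows(64, seed=3)
        nets = [
            NumpyMLP(X.shape[1], hidden_width=16, seed=5).fit(X, y, epochs=10)
            for _ in range(2)
        ]
        assert nets[0].weights_hash() == nets[1].weights_hash()
        assert np.array_equal(nets[0].predict(X), nets[1].predict(X))

    def test_zeroed_output_layer_predicts_zero(self):
        net = NumpyMLP(PAIR_WIDTH, hidden_width=8, seed=0)
        net.weights[-1][:] = 0.0
        net.biases[-1][:] = 0.0
        X, _ = _toy_rows(10)
        assert np.all(net.predict(X) == 0.0)

    def test_warm_start_requires_matching_shape(self):
        a = NumpyMLP(10, hidden_width=4, seed=0)
        b = NumpyMLP(10, hidden_width=8, seed=0)
        with pytest.raises(ValueError):
            b.load_weights_from(a)


class TestTrainRegressor:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_regressor("mlp", (np.empty((0, PAIR_WIDTH), np.float32), np.empty(0)))

    def test_inconsistent_width_rejected_naming_row(self):
        rows = [(np.zeros(PAIR_WIDTH), 0.0), (np.zeros(100), 0.0)]
        with pytest.raises(ValueError, match="row 1"):
            train_regressor("mlp", rows, MLPConfig(hidden_width=4, epochs=1))

    def test_training_pcc_near_one_on_learnable_truth(self):
        X, y = _toy_rows(256, seed=4)
        cfg = MLPConfig(hidden_width=64, epochs=200, batch_size=64, seed=0)
        model = train_regressor("mlp", (X, y), cfg)
        assert pcc(y, model.predict_raw(X)) >= 0.99

    @pytest.mark.parametrize("algorithm", ["rf", "gbx"])
    def test_comparators_share_the_contract(self, algorithm):
        X, y = _toy_rows(128, seed=5)
        cfg_cls = {"rf": RFConfig, "gbx": GBXConfig}[algorithm]
        model = train_regressor(algorithm, (X, y), cfg_cls(n_estimators=20, seed=1))
        pred = model.predict_symmetric(X)
        assert pred.shape == y.shape
        swapped = model.predict_symmetric(swap_pair_vector(X))
        assert np.array_equal(pred, swapped)


class TestSymmetricPrediction:
    def test_predict_pair_exactly_order_invariant_for_50_random_pairs(
        self, drug_compounds
    ):
        cfg = MLPConfig(hidden_width=16, epochs=3, batch_size=64, seed=0)
        X, y = _toy_rows(64, seed=6)
        model = train_regressor("mlp", (X, y), cfg)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.choice(len(drug_compounds), size=2, replace=False)
            a, b = drug_compounds[i], drug_compounds[j]
            assert predict_pair(model, a, b) == predict_pair(model, b, a)

    def test_self_pair_equals_raw_output(self, drug_compounds):
        cfg = MLPConfig(hidden_width=16, epochs=2, batch_size=64, seed=0)
        X, y = _toy_rows(64, seed=7)
        model = train_regressor("mlp", (X, y), cfg)
        c = drug_compounds[3]
        vec = featurize_pair(c, c).vector.astype(np.float32)
        assert predict_pair(model, c, c) == pytest.approx(
            float(model.predict_raw(vec)[0])
        )


class TestSerialization:
    @pytest.mark.parametrize("algorithm", ["mlp", "rf", "gbx"])
    def test_roundtrip_predictions_bit_identical(self, tmp_path, algorithm):
        X, y = _toy_rows(64, seed=8)
        cfg = (
            MLPConfig(hidden_width=16, epochs=5, seed=2)
            if algorithm == "mlp"
            else default_config(algorithm).__class__(n_estimators=10, seed=2)
        )
        model = train_regressor(algorithm, (X, y), cfg, cell_line="CELL_X")
        path = tmp_path / "m.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.cell_line == "CELL_X"
        assert loaded.config == model.config
        assert np.array_equal(loaded.predict_raw(X), model.predict_raw(X))

    def test_layout_mismatch_refused(self, tmp_path):
        X, y = _toy_rows(16, seed=9)
        model = train_regressor("mlp", (X, y), MLPConfig(hidden_width=4, epochs=1))
        path = tmp_path / "m.joblib"
        save_model(model, path)
        import joblib

        payload = joblib.load(path)
        payload["feature_layout"] = "pubchem881+morgan1024r2|pair3810"
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="feature layout"):
            load_model(path)


class TestHyperparameterTuning:
    def _cell(self, small_screen):
        _, ds = small_screen
        return ds.subset("CELL_A")

    def test_single_point_grid_gives_table_of_one(self, small_screen):
        from pairsyn.data import make_split_plan
        from pairsyn.models import tune_hyperparameters

        cell = self._cell(small_screen)
        plan = make_split_plan(cell, k=2, seed=0)
        base = MLPConfig(hidden_width=16, epochs=4, seed=0)
        table = tune_hyperparameters("mlp", {"hidden_width": [16]}, plan, cell, base)
        assert len(table) == 1

    def test_ranking_is_deterministic_and_width_matters(self, small_screen):
        from pairsyn.data import make_split_plan
        from pairsyn.models import tune_hyperparameters

        cell = self._cell(small_screen)
        plan = make_split_plan(cell, k=2, seed=1)
        base = MLPConfig(epochs=30, batch_size=128, seed=0)
        grid = {"hidden_width": [2, 128]}
        t1 = tune_hyperparameters("mlp", grid, plan, cell, base)
        t2 = tune_hyperparameters("mlp", grid, plan, cell, base)
        assert list(t1["mean_validation_pcc"]) == list(t2["mean_validation_pcc"])
        assert t1.iloc[0]["config"].hidden_width == 128


class TestFingerprintCombinationAxis:
    def test_masked_combinations_use_only_their_block(self):
        from pairsyn.models import fingerprint_mask
        from pairsyn.features import COMPOUND_WIDTH, PUBCHEM_WIDTH, PAIR_WIDTH

        pub = fingerprint_mask("pubchem")
        mor = fingerprint_mask("morgan")
        assert fingerprint_mask("pubchem+morgan") is None
        assert pub.sum() == 2 * PUBCHEM_WIDTH
        assert mor.sum() == PAIR_WIDTH - 2 * PUBCHEM_WIDTH
        assert np.all(pub + mor == 1.0)  # blocks partition the layout

    def test_predictions_ignore_the_masked_block(self):
        X, y = _toy_rows(64, seed=11)
        cfg = MLPConfig(hidden_width=16, epochs=5, fingerprints="pubchem", seed=0)
        model = train_regressor("mlp", (X, y), cfg)
        X2 = X.copy()
        rng = np.random.default_rng(0)
        from pairsyn.features import COMPOUND_WIDTH, PUBCHEM_WIDTH

        # scramble only the morgan columns; predictions must not move
        for off in (PUBCHEM_WIDTH, COMPOUND_WIDTH + PUBCHEM_WIDTH):
            X2[:, off : off + 1024] = rng.random((64, 1024))
        assert np.array_equal(model.predict_raw(X), model.predict_raw(X2))

    def test_combination_is_a_grid_axis(self, small_screen):
        from pairsyn.data import make_split_plan
        from pairsyn.models import tune_hyperparameters

        _, ds = small_screen
        cell = ds.subset("CELL_A")
        plan = make_split_plan(cell, k=2, seed=3)
        base = MLPConfig(hidden_width=32, epochs=6, batch_size=128, seed=0)
        table = tune_hyperparameters(
            "mlp", {"fingerprints": ["pubchem+morgan", "morgan"]}, plan, cell, base
        )
        assert len(table) == 2
        assert {c.fingerprints for c in table["config"]} == {
            "pubchem+morgan", "morgan"
        }
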