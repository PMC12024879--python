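"""Federated multi-task training: loss algebra, local updates, FedAvg,
degenerate federations, and the Model/Results surface."""

import numpy as np
import pytest

from ppglucose import nn, synth
from ppglucose.fl import (
    ClientDataset,
    FederatedGlucoseModel,
    FLConfig,
    TargetScaler,
    delta,
    fedavg,
    local_train,
    multitask_loss,
    predict,
    train_centralized,
    train_federated,
)
from ppglucose.nn import Architecture, ModelParams


def _toy_client(n=16, d=3, seed=0, client_id="c0"):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    w = np.array([2.0, -1.0, 0.5])[:d]
    y = 120 + 30 * (X @ w) + rng.normal(0, 1, n)
    classes = np.clip(np.digitize(y, [70, 180]), 0, 2)
    return ClientDataset(X, np.clip(y, 45, 395), classes, client_id=client_id)


def _linear_cfg(**kw):
    base = dict(
        n_clients=None, rounds=1, local_epochs=1, batch_size=10_000, learning_rate=0.05,
        optimizer="sgd", lambda_cls=0.0, dropout=0.0, n_layers=0,
        standardize_features=False, standardize_targets=False, seed=0,
    )
    base.update(kw)
    return FLConfig(**base)


class TestMultitaskLoss:
    def test_perfect_regression_zero_loss(self):
        probs = np.full((3, 3), 1 / 3)
        rep = multitask_loss([100, 150, 200], [100, 150, 200], probs, np.eye(3), 1.0, 0.0)
        assert rep.Lt == 0.0

    def test_confident_correct_classification_zero_ce(self):
        probs = np.eye(3)
        rep = multitask_loss(np.zeros(3), np.zeros(3), probs, np.eye(3), 0.0, 1.0)
        assert rep.Lc == pytest.approx(0.0, abs=1e-9)

    def test_ten_mgdl_error_gives_mse_100(self):
        probs = np.array([[1 / 3, 1 / 3, 1 / 3]])
        rep = multitask_loss([110.0], [100.0], probs, np.array([[0, 1, 0.0]]), 1.0, 0.0)
        assert rep.Lt == pytest.approx(100.0)
        assert rep.Lr == pytest.approx(100.0)

    def test_zero_probability_clipped_with_warning(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="clipping"):
            rep = multitask_loss([0.0], [0.0], probs, np.array([[0, 1, 0.0]]), 0.0, 1.0)
        assert np.isfinite(rep.Lc)

    def test_probability_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            multitask_loss([0.0], [0.0], np.array([[0.5, 0.1, 0.1]]), np.array([[1, 0, 0.0]]))


class TestGradients:
    @pytest.mark.parametrize(
        "arch",
        [
            Architecture("mlp", 5, 8, 2),
            Architecture("mlp", 5, 8, 0),
            Architecture("recurrent", 4, 6, 3, seq_len=5),
        ],
        ids=["mlp", "linear", "recurrent"],
    )
    def test_backprop_matches_finite_differences(self, arch):
        rng = np.random.default_rng(0)
        params = ModelParams.init(arch, rng)
        shape = (7, arch.input_dim) if arch.kind == "mlp" else (7, 5, arch.input_dim)
        X = rng.standard_normal(shape)
        y = rng.standard_normal(7)
        onehot = np.eye(3)[rng.integers(0, 3, 7)]
        _, grad = nn.loss_and_grad(params, X, y, onehot, 1.0, 1.0)
        eps = 1e-6
        idx = rng.choice(params.vector.size, size=min(60, params.vector.size), replace=False)
        for i in idx:
            v = params.vector.copy()
            v[i] += eps
            up, _ = nn.loss_and_grad(ModelParams(v, arch), X, y, onehot, 1.0, 1.0)
            v[i] -= 2 * eps
            dn, _ = nn.loss_and_grad(ModelParams(v, arch), X, y, onehot, 1.0, 1.0)
            assert (up - dn) / (2 * eps) == pytest.approx(grad[i], rel=1e-4, abs=1e-8)


class TestLocalTrain:
    def test_zero_learning_rate_is_identity(self):
        client = _toy_client()
        cfg = _linear_cfg(learning_rate=0.0)
        params = ModelParams.init(Architecture("mlp", 3, 0, 0), np.random.default_rng(0))
        out = local_train(params, client, cfg)
        assert np.array_equal(out.vector, params.vector)

    def test_convex_loss_decreases_under_full_batch_sgd(self):
        client = _toy_client(n=32)
        cfg = _linear_cfg(learning_rate=0.01, standardize_targets=True)
        scaler = TargetScaler.fit([client], cfg)
        arch = Architecture("mlp", 3, 0, 0)
        params = ModelParams.init(arch, np.random.default_rng(1))
        losses = []
        for _ in range(10):
            X, y, onehot = client.features, scaler.transform_y(client.bgl), client.onehot
            loss, _ = nn.loss_and_grad(params, X, y, onehot, 1.0, 0.0)
            losses.append(loss)
            params = local_train(params, client, cfg, scaler=scaler)
        assert np.all(np.diff(losses) < 0)

    def test_same_seed_reproduces_parameters(self):
        client = _toy_client()
        cfg = FLConfig(n_clients=None, rounds=1, seed=5)
        params = ModelParams.init(Architecture("mlp", 3, 16, 2), np.random.default_rng(2))
        a = local_train(params, client, cfg, seed=11)
        b = local_train(params, client, cfg, seed=11)
        assert np.array_equal(a.vector, b.vector)


class TestDeltaAndFedavg:
    def test_delta_identities(self):
        arch = Architecture("mlp", 2, 0, 0)
        rng = np.random.default_rng(0)
        a = ModelParams.init(arch, rng)
        b = ModelParams(a.vector + 1.5, arch)
        assert np.allclose(delta(a, a).vector, 0.0)
        assert np.allclose(delta(a, b).vector, -delta(b, a).vector)
        assert np.allclose(a.vector + delta(a, b).vector, b.vector)

    def test_equal_sizes_give_arithmetic_mean(self):
        arch = Architecture("mlp", 2, 0, 0)
        ps = [ModelParams(np.full(arch.n_params, v), arch) for v in (1.0, 3.0)]
        out = fedavg(ps, [100, 100])
        assert np.allclose(out.vector, 2.0)

    def test_size_weighted_average(self):
        arch = Architecture("mlp", 2, 0, 0)
        ps = [ModelParams(np.full(arch.n_params, 1.0), arch),
              ModelParams(np.full(arch.n_params, 3.0), arch)]
        out = fedavg(ps, [100, 300])
        assert np.allclose(out.vector, 2.5)

    def test_single_client_is_identity(self):
        arch = Architecture("mlp", 2, 4, 1)
        p = ModelParams.init(arch, np.random.default_rng(3))
        assert np.array_equal(fedavg([p], [7]).vector, p.vector)

    def test_aggregating_identical_vectors_conserves_them(self):
        arch = Architecture("mlp", 2, 4, 1)
        p = ModelParams.init(arch, np.random.default_rng(4))
        out = fedavg([p, p, p], [10, 20, 30])
        assert np.allclose(out.vector, p.vector, atol=1e-12)

    def test_raw_data_never_crosses_the_aggregation_boundary(self):
        """The server-side interface accepts ModelParams only."""
        with pytest.raises((AttributeError, ValueError, TypeError)):
            fedavg([np.ones(5), np.ones(5)], [1, 1])
        with pytest.raises(ValueError):
            fedavg([], [])

    def test_architecture_mismatch_rejected(self):
        a = ModelParams.init(Architecture("mlp", 2, 0, 0), np.random.default_rng(0))
        b = ModelParams.init(Architecture("mlp", 3, 0, 0), np.random.default_rng(0))
        with pytest.raises(ValueError):
            delta(a, b)
        with pytest.raises(ValueError):
            fedavg([a, b], [1, 1])


class TestTrainFederated:
    def test_single_client_equals_centralized_bit_for_bit(self):
        client = _toy_client(n=40)
        cfg = FLConfig(n_clients=1, rounds=3, local_epochs=2, seed=9)
        fed_params, history, _ = train_federated([client], cfg)
        central = train_centralized(client, cfg)
        assert np.array_equal(fed_params.vector, central.vector)
        assert len(history) == 3

    def test_single_sgd_round_matches_closed_form_pooled_step(self):
        """One full-batch SGD step per client with equal sizes equals
        the gradient step on the pooled data, computed analytically."""
        clients = [_toy_client(n=8, seed=s, client_id=f"c{s}") for s in range(2)]
        cfg = _linear_cfg(learning_rate=0.01)
        # initial parameters: the rounds=0 federation
        p0, _, _ = train_federated(clients, _linear_cfg(rounds=0))
        params, _, _ = train_federated(clients, cfg)

        parts = p0.unflatten()
        W, b = parts["Wr"].copy(), float(parts["br"])
        Xp = np.vstack([c.features for c in clients])
        yp = np.concatenate([c.bgl for c in clients])
        resid = Xp @ W + b - yp
        gW = 2.0 * Xp.T @ resid / yp.size
        gb = 2.0 * resid.mean()
        expected = parts.copy()
        expected["Wr"] = W - cfg.learning_rate * gW
        expected["br"] = np.asarray(b - cfg.learning_rate * gb)
        expected_vec = ModelParams.flatten(expected, p0.arch)
        assert np.allclose(params.vector, expected_vec, atol=1e-8)

    def test_round_history_length_and_reproducibility(self):
        clients = [_toy_client(seed=s, client_id=f"c{s}") for s in range(3)]
        cfg = FLConfig(n_clients=3, rounds=4, seed=2)
        p1, h1, _ = train_federated(clients, cfg)
        p2, h2, _ = train_federated(clients, cfg)
        assert len(h1) == 4
        assert np.array_equal(p1.vector, p2.vector)
        assert h1 == h2

    def test_zero_rounds_returns_initial_model(self):
        clients = [_toy_client()]
        params, history, scaler = train_federated(clients, FLConfig(n_clients=1, rounds=0))
        assert history == []
        bgl, cls_idx, probs = predict(params, clients[0].features, scaler)
        assert np.all(np.isfinite(bgl))
        assert probs.shape == (clients[0].size, 3)

    def test_trained_model_beats_predict_the_mean(self):
        wins = 0
        for seed in range(3):
            df = synth.planted_feature_matrix(300, d=6, informative=(0, 1), noise_sd=0.2, seed=seed)
            train, test = df.iloc[:240], df.iloc[240:]
            model = FederatedGlucoseModel.from_dataframe(
                train, n_clients=3, config=FLConfig(n_clients=3, rounds=20, seed=seed)
            )
            res = model.fit()
            pred = res.predict(test[[f"f{j}" for j in range(6)]].to_numpy())
            err = pred["bgl_pred_mgdl"].to_numpy() - test["bgl_mgdl"].to_numpy()
            rmse = np.sqrt(np.mean(err**2))
            baseline = np.sqrt(np.mean((train["bgl_mgdl"].mean() - test["bgl_mgdl"]) ** 2))
            wins += rmse < baseline
        assert wins == 3


class TestPredictAndResults:
    def test_argmax_class_decision(self):
        arch = Architecture("mlp", 2, 0, 0)
        parts = {name: np.zeros(shape) for name, shape in arch.param_shapes()}
        parts["bc"] = np.log(np.array([0.1, 0.7, 0.2]))
        params = ModelParams(ModelParams.flatten(parts, arch), arch)
        _, cls_idx, probs = predict(params, np.zeros((1, 2)))
        assert cls_idx[0] == 1
        assert probs[0] == pytest.approx([0.1, 0.7, 0.2])

    def test_inference_is_deterministic(self):
        client = _toy_client(n=30)
        res = FederatedGlucoseModel([client], FLConfig(n_clients=1, rounds=2, dropout=0.3)).fit()
        p1 = res.predict(client.features)
        p2 = res.predict(client.features)
        assert p1.equals(p2)

    def test_summary_mentions_configuration(self):
        client = _toy_client(n=30)
        res = FederatedGlucoseModel([client], FLConfig(n_clients=1, rounds=2)).fit()
        text = res.summary()
        assert "rounds" in text and "mlp" in text and "c0" in text

    def test_feature_mask_applied_before_training(self):
        client = _toy_client(n=30)
        model = FederatedGlucoseModel([client], FLConfig(n_clients=1, rounds=1),
                                      mask=np.array([1, 0, 1]))
        assert model.clients[0].features.shape[1] == 2


class TestRecurrentModel:
    def test_sequences_train_and_predict(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5, 4))
        y = 120 + 40 * X[:, :, 0].mean(axis=1)
        classes = np.clip(np.digitize(y, [70, 180]), 0, 2)
        client = ClientDataset(X, y, classes)
        cfg = FLConfig(n_clients=1, rounds=4, model_kind="recurrent", n_layers=3,
                       hidden_units=16, seq_len=5, seed=0)
        params, history, scaler = train_federated([client], cfg)
        assert len(history) == 4
        assert history[-1]["Lt"] < history[0]["Lt"]
        bgl, cls_idx, _ = predict(params, X, scaler)
        assert bgl.shape == (40,)
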