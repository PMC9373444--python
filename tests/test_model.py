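import numpy as np
import pytest

import circsplice as cs
from circsplice import _nn
from circsplice.errors import ArchitectureInfeasible, DegenerateLabels, LengthMismatch
from conftest import small_fixture, tiny_config


def brute_force_conv_scan(seq, kernel, bias):
    """Independent conv+ReLU oracle: explicit python loops over positions."""
    lookup = {"A": 0, "C": 1, "G": 2, "U": 3}
    w = len(kernel)
    out = []
    for start in range(len(seq) - w + 1):
        total = bias
        for j in range(w):
            base = seq[start + j]
            if base in lookup:
                total += kernel[j][lookup[base]]
        out.append(max(total, 0.0))
    return np.array(out)


class TestShapeContract:
    def test_default_config_reproduces_published_shapes(self):
        shapes = dict(cs.shape_contract(cs.ModelConfig()))
        assert shapes["input"] == (100, 4)
        assert shapes["conv1"] == (89, 256)
        assert shapes["conv2"] == (45, 128)
        assert shapes["maxpool"] == (9, 128)
        assert shapes["flatten"] == (1152,)
        assert shapes["concatenate"] == (2304,)

    def test_width_one_conv_preserves_length(self):
        cfg = cs.ModelConfig(conv1_size=1)
        assert dict(cs.shape_contract(cfg))["conv1"] == (100, cfg.conv1_kernels)

    def test_infeasible_architecture_rejected(self):
        with pytest.raises(ArchitectureInfeasible):
            cs.shape_contract(cs.ModelConfig(conv2_stride=30))

    def test_contract_matches_forward_pass_on_random_configs(self):
        """Shape oracle: analytic shapes equal observed activations."""
        rng = np.random.default_rng(0)
        pairs, _ = small_fixture(n=2)
        xa, xd, _ = cs.encode_pairs(pairs)
        for _ in range(200):
            cfg = cs.ModelConfig(
                conv1_kernels=int(rng.integers(1, 5)),
                conv1_size=int(rng.integers(1, 31)),
                conv2_kernels=int(rng.integers(1, 5)),
                conv2_size=int(rng.integers(1, 41)),
                conv2_stride=int(rng.integers(1, 4)),
                batchnorm=bool(rng.integers(0, 2)),
                seed=int(rng.integers(0, 1000)),
            )
            try:
                expected = dict(cs.shape_contract(cfg))
            except ArchitectureInfeasible:
                continue
            model = cs.build_model(cfg)
            _, _, inter = model.forward(xa, xd, collect=True)
            for layer in ("conv1", "conv2", "maxpool", "flatten"):
                assert inter["sa"][layer].shape[1:] == expected[layer], cfg
                assert inter["sd"][layer].shape[1:] == expected[layer], cfg
            assert inter["concatenate"].shape[1:] == expected["concatenate"]


class TestBuildModel:
    def test_same_seed_same_initial_predictions(self, tiny_dataset):
        pairs, _ = tiny_dataset
        a = cs.build_model(tiny_config(), seed=5)
        b = cs.build_model(tiny_config(), seed=5)
        np.testing.assert_array_equal(
            cs.predict(a, pairs[:10]), cs.predict(b, pairs[:10])
        )

    def test_branches_are_unshared(self):
        m = cs.build_model(tiny_config())
        assert not np.array_equal(m.params["sa_conv1_W"], m.params["sd_conv1_W"])

    def test_no_bn_variant_has_no_bn_parameters(self):
        m = cs.build_model(tiny_config().variant("no_bn"))
        assert "bn_gamma" not in m.params
        assert "bn_beta" not in m.params

    def test_variant_names(self):
        cfg = tiny_config()
        assert cfg.variant("default").batchnorm
        assert not cfg.variant("no_bn").batchnorm
        v = cfg.variant("bn_to_dropout")
        assert not v.batchnorm and v.bn_as_dropout
        with pytest.raises(ValueError):
            cfg.variant("nope")


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = cs.ModelConfig(
            conv1_kernels=3, conv1_size=5, conv2_kernels=2, conv2_size=7,
            dropout1=0.0, dropout2=0.0, batch_size=4, seed=3,
        )
        m = cs.build_model(cfg, seed=3)
        for k in m.params:
            m.params[k] = m.params[k].astype(np.float64)
        m.bn_mean = m.bn_mean.astype(np.float64)
        m.bn_var = m.bn_var.astype(np.float64)
        rng = np.random.default_rng(0)
        xa, xd = rng.random((4, 100, 4)), rng.random((4, 100, 4))
        y = np.array([0.0, 1.0, 1.0, 0.0])

        def loss():
            bm, bv = m.bn_mean.copy(), m.bn_var.copy()
            prob, cache, _ = m.forward(xa, xd, train=True)
            m.bn_mean, m.bn_var = bm, bv
            return _nn.bce_loss(prob, y), prob, cache

        base, prob, cache = loss()
        grads = m.backward(prob, y, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(5)
        for key in m.params:
            flat = m.params[key].ravel()
            g = np.asarray(grads[key]).ravel()
            for i in check_rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                up, _, _ = loss()
                flat[i] = old - eps
                down, _, _ = loss()
                flat[i] = old
                numeric = (up - down) / (2 * eps)
                if abs(numeric) + abs(g[i]) > 1e-8:
                    assert abs(numeric - g[i]) / (abs(numeric) + abs(g[i])) < 1e-4

    def test_single_step_decreases_batch_loss(self):
        pairs, _ = small_fixture(n=32)
        xa, xd, y = cs.encode_pairs(pairs)
        cfg = tiny_config(dropout1=0.0, dropout2=0.0, learning_rate=1e-4)
        m = cs.build_model(cfg)
        opt = _nn.RMSProp(m.params, lr=cfg.learning_rate)
        prob, cache, _ = m.forward(xa, xd, train=True)
        before = _nn.bce_loss(prob, y)
        opt.step(m.params, m.backward(prob, y, cache))
        prob_after, _, _ = m.forward(xa, xd, train=True)
        assert _nn.bce_loss(prob_after, y) < before


class TestTraining:
    def test_separable_fixture_reaches_high_training_accuracy(
        self, tiny_dataset, tiny_trained
    ):
        pairs, _ = tiny_dataset
        prob = cs.predict(tiny_trained, pairs)
        labels = np.array([p.label for p in pairs])
        acc = np.mean((prob >= 0.5) == labels)
        assert acc >= 0.95

    def test_epoch_budget_respected(self, tiny_trained):
        assert tiny_trained.stopped_epoch_ <= tiny_trained.config.max_epochs
        assert len(tiny_trained.history) == tiny_trained.stopped_epoch_

    def test_single_class_training_rejected(self, tiny_dataset):
        pairs, _ = tiny_dataset
        positives = [p for p in pairs if p.label == 1]
        with pytest.raises(DegenerateLabels):
            cs.train(cs.build_model(tiny_config()), positives)

    def test_zero_patience_stops_after_first_non_improvement(self, tiny_dataset):
        pairs, _ = tiny_dataset
        # lr=0 freezes parameters, so epoch 2 cannot improve on epoch 1
        cfg = tiny_config(learning_rate=0.0, early_stopping_patience=0, max_epochs=10)
        m = cs.train(cs.build_model(cfg), pairs)
        assert m.best_epoch_ == 1
        assert m.stopped_epoch_ == 2

    def test_early_stop_within_patience_and_best_weights_restored(self, tiny_dataset):
        pairs, _ = tiny_dataset
        val = pairs[::4]
        tr = [p for p in pairs if p not in val]
        cfg = tiny_config(max_epochs=12, early_stopping_patience=3)
        m = cs.train(cs.build_model(cfg), tr, val_pairs=val)
        assert m.stopped_epoch_ - m.best_epoch_ <= cfg.early_stopping_patience
        # restored parameters reproduce the best recorded validation loss
        xa, xd, y = cs.encode_pairs(val)
        val_loss = _nn.bce_loss(m.predict_arrays(xa, xd), y)
        best = min(h["val_loss"] for h in m.history)
        assert np.isclose(val_loss, best, rtol=1e-6)
        assert m.param_hash() == m.best_param_hash_


class TestPredict:
    def test_outputs_in_unit_interval(self, tiny_trained, tiny_dataset):
        pairs, _ = tiny_dataset
        prob = cs.predict(tiny_trained, pairs)
        assert np.all((prob >= 0) & (prob <= 1))

    def test_batching_invariance(self, tiny_trained, tiny_dataset):
        pairs, _ = tiny_dataset
        whole = cs.predict(tiny_trained, pairs)
        parts = np.concatenate(
            [cs.predict(tiny_trained, pairs[:50]), cs.predict(tiny_trained, pairs[50:])]
        )
        np.testing.assert_allclose(whole, parts, rtol=1e-6)

    def test_wrong_shape_rejected(self, tiny_trained):
        with pytest.raises(LengthMismatch):
            tiny_trained.predict_arrays(np.zeros((2, 99, 4)), np.zeros((2, 99, 4)))

    def test_save_load_round_trip_preserves_predictions(
        self, tmp_path, tiny_trained, tiny_dataset
    ):
        pairs, _ = tiny_dataset
        path = tmp_path / "model.npz"
        tiny_trained.save(path)
        back = cs.TrainedModel.load(path)
        assert back.param_hash() == tiny_trained.param_hash()
        np.testing.assert_array_equal(
            cs.predict(back, pairs[:20]), cs.predict(tiny_trained, pairs[:20])
        )
        assert back.config == tiny_trained.config


class TestFirstLayerActivations:
    def test_shape_and_nonnegativity(self, tiny_trained, tiny_dataset):
        pairs, _ = tiny_dataset
        acts = cs.first_layer_activations(tiny_trained, pairs[:10], "SA")
        cfg = tiny_trained.config
        assert acts.shape == (10, 100 - cfg.conv1_size + 1, cfg.conv1_kernels)
        assert np.all(acts >= 0)

    def test_handcrafted_kernel_agrees_with_brute_force_scan(self, tiny_dataset):
        pairs, _ = tiny_dataset
        cfg = tiny_config()
        m = cs.build_model(cfg)
        # kernel 0 rewards the consensus UGCAUG, one unit per matching base
        consensus = "UGCAUG"
        lookup = {"A": 0, "C": 1, "G": 2, "U": 3}
        W = np.zeros((cfg.conv1_size, 4, cfg.conv1_kernels), dtype=np.float32)
        for j, base in enumerate(consensus):
            W[j, lookup[base], 0] = 1.0
        m.params["sa_conv1_W"] = W
        m.params["sa_conv1_b"] = np.zeros(cfg.conv1_kernels, dtype=np.float32)
        kernel = [[W[j, c, 0] for c in range(4)] for j in range(cfg.conv1_size)]
        acts = cs.first_layer_activations(m, pairs[:15], "SA")[:, :, 0]
        for i, p in enumerate(pairs[:15]):
            expected = brute_force_conv_scan(p.sa_seq, kernel, 0.0)
            np.testing.assert_allclose(acts[i], expected, atol=1e-5)

    def test_planted_consensus_is_the_top_activation(self, tiny_dataset):
        pairs, log = tiny_dataset
        cfg = tiny_config()
        m = cs.build_model(cfg)
        lookup = {"A": 0, "C": 1, "G": 2, "U": 3}
        W = np.full((cfg.conv1_size, 4, cfg.conv1_kernels), -1.0, dtype=np.float32)
        for j, base in enumerate("UGCAUG"):
            W[j, lookup[base], 0] = 1.0
        m.params["sa_conv1_W"] = W
        planted = set(log[log.input == "SA"].id)
        acts = cs.first_layer_activations(m, pairs, "SA")[:, :, 0]
        for i, p in enumerate(pairs):
            if p.id in planted and "UGCAUG" in p.sa_seq:
                assert p.sa_seq[int(acts[i].argmax()) :][:6] == "UGCAUG"
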