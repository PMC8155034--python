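"""GCN/CNN forward math against hand computations and brute-force oracles;
training-loop contracts (early stopping, determinism, masking, gradients)."""

import numpy as np
import pytest

from strucfun.features import one_hot_encode
from strucfun.model import (CNNConfig, CNNModel, GCNConfig, GCNModel,
                            TrainConfig, concat_and_pool, graph_conv_layer,
                            normalize_adjacency, predict, prepare_gcn_inputs,
                            train_model, weighted_bce_loss)
from strucfun.nn import EarlyStopper
from strucfun.ontology import labels_to_pairs


def random_adjacency(rng, n, p=0.4):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    return a + a.T


class TestNormalizeAdjacency:
    def test_isolated_node(self):
        assert np.allclose(normalize_adjacency([[0]]), [[1.0]])

    def test_two_node_edge(self):
        out = normalize_adjacency([[0, 1], [1, 0]])
        assert np.allclose(out, 0.5)

    def test_path_graph_hand_values(self):
        out = normalize_adjacency([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert np.isclose(out[0, 1], 1 / np.sqrt(6))
        assert np.isclose(out[0, 0], 0.5)
        assert np.isclose(out[1, 1], 1 / 3)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency([[0, 1], [0, 0]])

    def test_spectral_bound_largest_eigenvalue_is_one(self):
        rng = np.random.default_rng(12)
        for n in (5, 12, 30):
            a_hat = normalize_adjacency(random_adjacency(rng, n))
            lam = np.linalg.eigvalsh(a_hat).max()
            assert np.isclose(lam, 1.0, atol=1e-10)


class TestGraphConvLayer:
    def test_identity_propagation(self):
        h = np.random.default_rng(0).normal(size=(4, 3))
        out = graph_conv_layer(np.eye(4), h, np.eye(3))
        assert np.allclose(out, np.maximum(h, 0))

    def test_relu_zeroes_negatives(self):
        h = -np.ones((3, 2))
        out = graph_conv_layer(np.eye(3), h, np.eye(2))
        assert np.all(out == 0)

    def test_matches_triple_product_oracle(self):
        rng = np.random.default_rng(1)
        a_hat = normalize_adjacency(random_adjacency(rng, 5))
        h = rng.normal(size=(5, 4))
        w = rng.normal(size=(4, 6))
        expected = np.maximum(a_hat @ h @ w, 0)
        assert np.allclose(graph_conv_layer(a_hat, h, w), expected,
                           atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_conv_layer(np.eye(3), np.zeros((4, 2)), np.zeros((2, 2)))


class TestConcatAndPool:
    def test_single_residue(self):
        out = concat_and_pool([np.array([[1.0, 2.0]]), np.array([[3.0]])])
        assert np.allclose(out, [1, 2, 3])

    def test_zero_features(self):
        assert np.allclose(concat_and_pool([np.zeros((5, 4))]), 0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        h1, h2 = rng.normal(size=(8, 3)), rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        a = concat_and_pool([h1, h2])
        b = concat_and_pool([h1[perm], h2[perm]])
        assert np.allclose(a, b)

    def test_mask_excludes_padding(self):
        h = np.ones((4, 2))
        mask = np.array([1, 1, 0, 0])
        assert np.allclose(concat_and_pool([h], mask), [2, 2])

    def test_inconsistent_rows_rejected(self):
        with pytest.raises(ValueError):
            concat_and_pool([np.zeros((3, 1)), np.zeros((4, 1))])


class TestClassify:
    def test_fresh_model_outputs_half(self):
        # zero head at init -> equal logits -> (0.5, 0.5) per term
        m = GCNModel(4, GCNConfig(channels=(8,), input_channels=8,
                                  fc_hidden=8), seed=0)
        x = one_hot_encode("ACDEFG")
        a_hat = normalize_adjacency(random_adjacency(np.random.default_rng(0), 6))
        probs, _ = m.forward(x, a_hat)
        assert np.allclose(probs.data, 0.5)

    def test_softmax_pairs_sum_to_one(self):
        rng = np.random.default_rng(5)
        m = GCNModel(3, GCNConfig(channels=(8, 8), input_channels=8,
                                  fc_hidden=8), seed=1)
        m.params["W_head"].data = rng.normal(size=m.params["W_head"].shape)
        x = one_hot_encode("ACDEFGHIK")
        a_hat = normalize_adjacency(random_adjacency(rng, 9))
        probs, _ = m.forward(x, a_hat)
        assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((probs.data >= 0) & (probs.data <= 1))

    def test_shift_invariance_of_softmax_pairs(self):
        rng = np.random.default_rng(6)
        m = GCNModel(3, GCNConfig(channels=(8,), input_channels=8,
                                  fc_hidden=8), seed=1)
        m.params["W_head"].data = rng.normal(size=m.params["W_head"].shape)
        x = one_hot_encode("ACDEFGH")
        a_hat = normalize_adjacency(random_adjacency(rng, 7))
        before, _ = m.forward(x, a_hat)
        # add the same constant to both logits of term 1
        m.params["b_head"].data[2:4] += 7.3
        after, _ = m.forward(x, a_hat)
        assert np.allclose(before.data, after.data, atol=1e-9)


class TestWeightedLoss:
    def test_perfect_prediction_loss_near_zero(self):
        y = labels_to_pairs(np.array([[1, 0], [0, 1]]))
        y_hat = y.astype(float)
        assert weighted_bce_loss(y_hat, y, np.ones(2)) < 1e-5

    def test_hand_computed_value(self):
        # 2 proteins, 1 term, N+ = 1 -> w = 2; natural-log convention
        y = labels_to_pairs(np.array([[1], [0]]))
        y_hat = np.array([[[0.9, 0.1]], [[0.2, 0.8]]])
        loss = weighted_bce_loss(y_hat, y, np.array([2.0]))
        expected = -(1 / 2) * (2 * np.log(0.9) + 2 * np.log(0.8))
        assert np.isclose(loss, expected)
        assert np.isclose(loss, 0.3285, atol=1e-4)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(7)
        y = labels_to_pairs((rng.random((4, 3)) < 0.5).astype(int))
        p = rng.random((4, 3, 1))
        y_hat = np.concatenate([p, 1 - p], axis=2)
        w = rng.random(3) + 0.5
        assert np.isclose(weighted_bce_loss(y_hat, y, 2 * w),
                          2 * weighted_bce_loss(y_hat, y, w))


class TestEarlyStopping:
    def test_patience_schedule(self):
        # losses 1.0, .9, .91...95: best at epoch 2, stop after epoch 7
        stopper = EarlyStopper(patience=5)
        stops = [stopper.update(v)
                 for v in (1.0, 0.9, 0.91, 0.92, 0.93, 0.94, 0.95)]
        assert stops == [False] * 6 + [True]
        assert stopper.best_epoch == 2


@pytest.fixture(scope="module")
def overfit_setup(tiny_dataset):
    records, space = tiny_dataset
    subset = records[:10]
    inputs = prepare_gcn_inputs(subset)
    labels = np.stack([r.labels for r in subset])
    return inputs, labels, space


class TestTraining:
    def cfg(self, **kw):
        base = dict(lr=3e-3, beta1=0.9, beta2=0.999, batch_size=8,
                    max_epochs=60, patience=60, seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def test_overfits_tiny_dataset(self, overfit_setup):
        inputs, labels, space = overfit_setup
        m = GCNModel(len(space), GCNConfig(channels=(16, 16), input_channels=16,
                                           fc_hidden=16), seed=0)
        state = train_model(m, inputs, labels, space.weight_vector, self.cfg())
        hist = state.log["history"]
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_deterministic_given_seed(self, overfit_setup):
        inputs, labels, space = overfit_setup
        params = []
        for _ in range(2):
            m = GCNModel(len(space), GCNConfig(channels=(8,), input_channels=8,
                                               fc_hidden=8), seed=3)
            train_model(m, inputs, labels, space.weight_vector,
                        self.cfg(max_epochs=10))
            params.append({k: v.data.copy() for k, v in m.params.items()})
        for k in params[0]:
            assert np.array_equal(params[0][k], params[1][k]), k

    def test_best_checkpoint_restored(self, overfit_setup):
        inputs, labels, space = overfit_setup
        m = GCNModel(len(space), GCNConfig(channels=(8,), input_channels=8,
                                           fc_hidden=8), seed=1)
        state = train_model(m, inputs, labels, space.weight_vector,
                            self.cfg(max_epochs=25, patience=3, min_epochs=1))
        best = state.log["best_epoch"]
        assert best <= state.log["stopped_epoch"]
        assert np.isclose(
            state.log["best_val_loss"],
            min(h["val_loss"] for h in state.log["history"]))


class TestPredictionContracts:
    def test_scores_in_unit_interval_and_strict_threshold(self, tiny_trained):
        model, records, inputs, labels, space, _ = tiny_trained
        scores, calls = predict(model, inputs[0])
        assert np.all((scores >= 0) & (scores <= 1))
        assert np.array_equal(calls, scores > 0.5)
        # a score of exactly 0.5 is a negative call
        assert not (np.float64(0.5) > 0.5)

    def test_permutation_invariance(self, tiny_trained):
        model, records, inputs, labels, space, _ = tiny_trained
        inp = inputs[0]
        rng = np.random.default_rng(0)
        L = inp["x"].shape[0]
        perm = rng.permutation(L)
        base = model.scores(inp)
        permuted = model.scores({
            "x": inp["x"][perm],
            "a_hat": inp["a_hat"][np.ix_(perm, perm)],
        })
        assert np.allclose(base, permuted, atol=1e-6)

    def test_masked_padding_changes_nothing(self, tiny_trained):
        model, records, inputs, labels, space, _ = tiny_trained
        inp = inputs[0]
        L = inp["x"].shape[0]
        pad = 7
        x_pad = np.vstack([inp["x"], np.zeros((pad, 26))])
        x_pad[L:, -1] = 1.0  # padded rows carry the gap channel
        a = np.zeros((L + pad, L + pad))
        # reconstruct the raw adjacency before re-normalizing the padded one
        raw = (inputs[0]["a_hat"] > 0).astype(int)
        np.fill_diagonal(raw, 0)
        a[:L, :L] = raw
        from strucfun.model import normalize_adjacency
        mask = np.concatenate([np.ones(L), np.zeros(pad)])
        padded_scores = model.scores({"x": x_pad,
                                      "a_hat": normalize_adjacency(a),
                                      "mask": mask})
        assert np.allclose(padded_scores, model.scores(inp), atol=1e-6)


class TestLossGradients:
    def test_analytic_gradient_matches_finite_differences(self, tiny_dataset):
        records, space = tiny_dataset
        rec = records[0]
        inputs = prepare_gcn_inputs([rec])[0]
        y_pairs = labels_to_pairs(rec.labels[None, :])[0].astype(float)
        w = space.weight_vector
        m = GCNModel(len(space), GCNConfig(channels=(6, 6), input_channels=6,
                                           fc_hidden=6), seed=2)
        rng = np.random.default_rng(0)
        # nonzero head so gradients reach every layer
        m.params["W_head"].data = 0.1 * rng.normal(
            size=m.params["W_head"].shape)
        for p in m.params.values():
            p.zero_grad()
        loss = m.loss(inputs, y_pairs, w)
        loss.backward()
        eps = 1e-5
        for name in ("W_conv0", "W_x", "W_fc", "W_head", "b_head"):
            param = m.params[name]
            flat = param.data.ravel()
            for k in rng.choice(flat.size, size=3, replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                up = float(m.loss(inputs, y_pairs, w).data)
                flat[k] = orig - eps
                down = float(m.loss(inputs, y_pairs, w).data)
                flat[k] = orig
                num = (up - down) / (2 * eps)
                ana = param.grad.ravel()[k]
                denom = max(abs(num), abs(ana), 1e-8)
                assert abs(num - ana) / denom < 1e-4, name


class TestCNNBaseline:
    def test_outputs_are_probabilities(self):
        m = CNNModel(4, seed=0)
        x = one_hot_encode("ACDEFGHIKLMNPQRSTVWY" * 3)
        probs = m.forward(x).data
        assert probs.shape == (4,)
        assert np.all((probs > 0) & (probs < 1))

    def test_width_one_identity_filter_maxpools_channels(self):
        cfg = CNNConfig(filter_widths=(1,), n_filters=26)
        m = CNNModel(2, cfg, seed=0)
        m.params["W_conv1"].data = np.eye(26)
        m.params["b_conv1"].data = np.zeros(26)
        x = one_hot_encode("AAC" + "D" * 30)
        feats = m.features(x).data
        expected = x.max(axis=0)  # per-channel presence indicator
        assert np.allclose(feats, expected)

    def test_shift_covariance_on_periodic_sequence(self):
        # non-negative filters: zero-padded edge windows cannot beat interior
        # windows, so max-pooled features are exactly shift-invariant on a
        # periodic sequence shifted by its period
        m = CNNModel(2, CNNConfig(filter_widths=(4, 8), n_filters=16), seed=1)
        for w in (4, 8):
            m.params[f"W_conv{w}"].data = np.abs(m.params[f"W_conv{w}"].data)
        base = "ACDEW"
        seq = base * 40
        shifted = seq[len(base):] + seq[:len(base)]
        f1 = m.features(one_hot_encode(seq)).data
        f2 = m.features(one_hot_encode(shifted)).data
        assert np.allclose(f1, f2)

    def test_short_sequence_zero_padded_with_warning(self, caplog):
        m = CNNModel(2, seed=0)
        with caplog.at_level("WARNING"):
            probs = m.forward(one_hot_encode("ACDE")).data
        assert probs.shape == (2,)
        assert "zero-padding" in caplog.text
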