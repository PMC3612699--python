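"""Two-phase contrastive learning, cross-entropy with tolerance, and the
backpropagation comparison networks."""

import numpy as np
import pytest

import recurvis as rv
from recurvis.errors import ConfigurationError
from recurvis.learning import (BpNetwork, TrainProtocol, bp_spec,
                               bp_train_trial, chl_update, cross_entropy)


class TestChl:

    def test_null_update_when_phases_match(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (5, 4))
        x = rng.uniform(0, 1, 5)
        y = rng.uniform(0, 1, 4)
        dw = chl_update(w, x, y, x, y, lrate=0.1, hebb_mix=0.0)
        assert np.allclose(dw, 0.0)

    def test_closed_form_with_soft_bounding(self):
        w = np.array([[0.5]])
        dw = chl_update(w, np.zeros(1), np.zeros(1), np.ones(1), np.ones(1),
                        lrate=0.1, hebb_mix=0.0)
        assert dw[0, 0] == pytest.approx(0.05)

    def test_pure_hebbian_null_at_weight_equilibrium(self):
        w = np.full((3, 2), 0.7)
        x = np.full(3, 0.7)              # x+ equals w: hebbian term vanishes
        y = np.ones(2)
        dw = chl_update(w, x, y, x, y, lrate=0.1, hebb_mix=1.0)
        assert np.allclose(dw, 0.0)

    def test_zero_learning_rate_gives_zero_delta(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 1, (4, 4))
        dw = chl_update(w, rng.random(4), rng.random(4), rng.random(4),
                        rng.random(4), lrate=0.0, hebb_mix=0.3)
        assert np.allclose(dw, 0.0)

    def test_soft_bounding_keeps_weights_in_unit_interval(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0, 1, (6, 6))
        for _ in range(500):
            args = [rng.random(6) for _ in range(4)]
            w = w + chl_update(w, *args, lrate=0.5, hebb_mix=0.1)
            assert w.min() >= 0 and w.max() <= 1

    def test_reciprocal_symmetry(self):
        """Swapping sender and receiver phase activities yields the
        transposed delta, so symmetric initial weights stay symmetric."""
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1, (5, 5))
        w = (w + w.T) / 2
        xm, ym, xp, yp = (rng.random(5) for _ in range(4))
        fwd = chl_update(w, xm, ym, xp, yp, lrate=0.1, hebb_mix=0.0)
        bwd = chl_update(w.T, ym, xm, yp, xp, lrate=0.1, hebb_mix=0.0)
        assert np.allclose(fwd, bwd.T)


class TestCrossEntropy:

    def test_half_output_single_unit(self):
        ce, _ = cross_entropy(np.array([1.0]), np.array([0.5]), tolerance=0.0)
        assert ce == pytest.approx(0.6931, abs=1e-4)

    def test_within_tolerance_gradient_is_zero(self):
        ce, grad = cross_entropy(np.array([1.0, 0.0]), np.array([0.96, 0.3]),
                                 tolerance=0.05)
        assert grad[0] == 0.0 and grad[1] != 0.0
        assert ce > 0                      # loss itself is not gated

    def test_matching_output_zero_gradient(self):
        t = np.array([0.2, 0.8])
        _, grad = cross_entropy(t, t + 0.01, tolerance=0.05)
        assert np.allclose(grad, 0.0)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = (rng.random(6) < 0.3).astype(float)
            o = rng.uniform(0.01, 0.99, 6)
            ce, _ = cross_entropy(t, o)
            assert ce >= 0


class TestBpNetworks:

    def test_variant_bundles(self):
        sp = bp_spec("sparse", (10, 8, 4))
        di = bp_spec("distrib", (10, 8, 4))
        assert sp.bias_init == -3.0 and sp.lrate == 0.2 and sp.kwta_input
        assert di.bias_init == 0.0 and di.lrate == 0.01 and not di.kwta_input
        with pytest.raises(ConfigurationError):
            bp_spec("other", (4, 2))

    def test_same_seed_identical_init(self):
        a = BpNetwork(bp_spec("sparse", (6, 5, 3)), seed=7)
        b = BpNetwork(bp_spec("sparse", (6, 5, 3)), seed=7)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_sparse_variant_has_much_lower_initial_activity(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 50)
        sp = BpNetwork(bp_spec("sparse", (50, 40, 5)), seed=0)
        di = BpNetwork(bp_spec("distrib", (50, 40, 5)), seed=0)
        act_sp = sp.forward(x)[1].mean()
        act_di = di.forward(x)[1].mean()
        assert act_sp < 0.25 * act_di

    def test_gradient_matches_finite_differences(self):
        """Central-difference oracle on a random small net, tolerance 0."""
        spec = bp_spec("distrib", (7, 5, 3))
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 7)
        t = np.array([1.0, 0.0, 0.0])

        def loss(net):
            return cross_entropy(t, net.forward(x)[-1], tolerance=0.0)[0]

        net = BpNetwork(spec, seed=1)
        acts = net.forward(x)
        delta = acts[-1] - t
        deltas = [delta]
        for layer in range(len(net.weights) - 1, 0, -1):
            a = acts[layer]
            deltas.insert(0, (deltas[0] @ net.weights[layer].T) * a * (1 - a))
        eps = 1e-6
        for layer in range(len(net.weights)):
            analytic = np.outer(acts[layer], deltas[layer])
            for idx in [(0, 0), (2, 1), (-1, -1)]:
                w0 = net.weights[layer][idx]
                net.weights[layer][idx] = w0 + eps
                up = loss(net)
                net.weights[layer][idx] = w0 - eps
                down = loss(net)
                net.weights[layer][idx] = w0
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(analytic[idx], rel=1e-4, abs=1e-8)

    def test_toy_task_loss_decreases(self):
        rng = np.random.default_rng(7)
        xa = rng.uniform(0.6, 1.0, (20, 6)) * np.array([1, 1, 1, 0, 0, 0])
        xb = rng.uniform(0.6, 1.0, (20, 6)) * np.array([0, 0, 0, 1, 1, 1])
        X = np.vstack([xa, xb])
        T = np.zeros((40, 2))
        T[:20, 0] = 1
        T[20:, 1] = 1
        net = BpNetwork(bp_spec("sparse", (6, 6, 2)), seed=2)
        losses = []
        for epoch in range(30):
            tot = 0.0
            for i in rng.permutation(40):
                tot += bp_train_trial(net, X[i], T[i])["loss"]
            losses.append(tot / 40)
        assert np.mean(losses[-5:]) < 0.3 * np.mean(losses[:5])

    def test_full_tolerance_freezes_weights(self):
        net = BpNetwork(bp_spec("sparse", (5, 4, 2)), seed=3)
        before = [w.copy() for w in net.weights]
        rng = np.random.default_rng(8)
        for _ in range(10):
            bp_train_trial(net, rng.random(5), np.array([1.0, 0.0]),
                           tolerance=1.0)
        for w0, w1 in zip(before, net.weights):
            assert np.array_equal(w0, w1)


class TestRecurrentTraining:

    def test_protocol_validation(self):
        with pytest.raises(ConfigurationError):
            TrainProtocol(lrate=0.0)
        with pytest.raises(ConfigurationError):
            TrainProtocol(hebb_mix=1.5)

    def test_tiny_task_memorised_within_50_epochs(self):
        """3 categories x 2 exemplars: the recurrent learner reaches 100%
        (augmented minus-phase) accuracy well inside 50 epochs."""
        spec = rv.SyntheticDatasetSpec(n_categories=3, exemplars_per_category=2,
                                       renders_per_exemplar=2, image_size=24,
                                       seed=1)
        manifest, images = rv.make_synthetic_dataset(spec)
        clf = rv.RecurrentVisualClassifier(
            epochs=50, seed=0, pool_size=4, v2_size=60, v2_k=15,
            it_size=40, it_k=8, stop_at_train_acc=100.0)
        clf.fit(images, manifest["category"].values)
        assert clf.history_["train_acc"].iloc[-1] == 100.0
        assert len(clf.history_) <= 50

    def test_unknown_category_rejected(self):
        spec = rv.SyntheticDatasetSpec(n_categories=2, exemplars_per_category=1,
                                       renders_per_exemplar=1, image_size=24)
        manifest, images = rv.make_synthetic_dataset(spec)
        clf = rv.RecurrentVisualClassifier(epochs=1, seed=0, v2_size=30, v2_k=6,
                                           it_size=20, it_k=4)
        clf.fit(images, manifest["category"].values)
        from recurvis.learning import train_trial
        with pytest.raises(Exception, match="unknown category"):
            train_trial(clf.model_, images[0], "nope", TrainProtocol(epochs=1),
                        np.random.default_rng(0))
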