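"""Network grid, forward pass, analytic Jacobian, and the
Levenberg-Marquardt trainer with early stopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstage import ann


def _fd_jacobian(net, X, eps=1e-6):
    """Central finite-difference Jacobian oracle."""
    theta = net.pack()
    J = np.zeros((X.shape[0] * net.topology.n_outputs, theta.size))
    for i in range(theta.size):
        plus, minus = net.copy(), net.copy()
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        plus.unpack(tp)
        minus.unpack(tm)
        J[:, i] = ((ann.forward(plus, X) - ann.forward(minus, X)) / (2 * eps)).ravel()
    return J


class TestTopologyGrid:
    def test_grid_has_exactly_six_members(self):
        topos = ann.build_topologies(9, 2)
        assert len(topos) == 6
        assert {(t.n_hidden_layers, t.n1) for t in topos} == {
            (1, 20), (1, 50), (2, 20), (2, 50), (3, 20), (3, 50),
        }

    @pytest.mark.parametrize(
        "L,n1,expected",
        [(2, 20, (20, 10)), (3, 50, (50, 25, 16)), (1, 50, (50,)), (3, 20, (20, 10, 6))],
    )
    def test_hidden_width_rule(self, L, n1, expected):
        topo = ann.NetworkTopology(L, n1, n_inputs=4, n_outputs=2)
        assert topo.hidden_widths == expected

    def test_widths_nonincreasing(self):
        for topo in ann.build_topologies(3, 4):
            w = topo.hidden_widths
            assert all(a >= b for a, b in zip(w, w[1:]))

    def test_invalid_grid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ann.build_topologies(0, 2)
        with pytest.raises(ValueError):
            ann.build_topologies(4, 1)


class TestForward:
    def test_zero_weights_output_biases(self):
        topo = ann.NetworkTopology(2, 20, n_inputs=3, n_outputs=2)
        net = ann.init_network(topo, np.random.default_rng(0))
        for W in net.weights:
            W[:] = 0.0
        net.biases[-1][:] = [0.7, -0.2]
        for b in net.biases[:-1]:
            b[:] = 0.0
        out = ann.forward(net, np.random.default_rng(1).normal(size=(4, 3)))
        np.testing.assert_allclose(out, np.tile([0.7, -0.2], (4, 1)))

    def test_forward_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        topo = ann.NetworkTopology(1, 20, n_inputs=2, n_outputs=3)
        net = ann.init_network(topo, rng)
        X = rng.normal(size=(5, 2))
        expected = np.tanh(X @ net.weights[0].T + net.biases[0]) @ net.weights[1].T + net.biases[1]
        np.testing.assert_allclose(ann.forward(net, X), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        topo = ann.NetworkTopology(1, 20, n_inputs=3, n_outputs=2)
        net = ann.init_network(topo, np.random.default_rng(0))
        with pytest.raises(ValueError, match="dimension"):
            ann.forward(net, np.zeros((2, 5)))

    def test_init_is_seed_deterministic(self):
        topo = ann.NetworkTopology(3, 50, n_inputs=4, n_outputs=2)
        a = ann.init_network(topo, np.random.default_rng(7))
        b = ann.init_network(topo, np.random.default_rng(7))
        np.testing.assert_array_equal(a.pack(), b.pack())


class TestJacobian:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        L=st.integers(1, 3),
        n_in=st.integers(1, 4),
        n_out=st.integers(2, 4),
    )
    def test_matches_central_finite_differences(self, seed, L, n_in, n_out):
        rng = np.random.default_rng(seed)
        topo = ann.NetworkTopology(L, 20, n_inputs=n_in, n_outputs=n_out)
        # shrink widths for the oracle's cost: rebuild tiny weights directly
        net = ann.init_network(
            ann.NetworkTopology(L, 20, n_inputs=n_in, n_outputs=n_out), rng
        )
        X = rng.normal(size=(3, n_in))
        J = ann.jacobian(net, X)
        Jfd = _fd_jacobian(net, X)
        rel = np.abs(J - Jfd).max() / max(np.abs(Jfd).max(), 1e-12)
        assert rel < 1e-6


class TestOneHot:
    def test_round_trip(self):
        T = ann.one_hot(np.array([0, 2, 1, 3]), 4)
        np.testing.assert_array_equal(T.argmax(axis=1), [0, 2, 1, 3])
        np.testing.assert_allclose(T.sum(axis=1), 1.0)

    def test_tie_decodes_to_lowest_class(self):
        topo = ann.NetworkTopology(1, 20, n_inputs=2, n_outputs=2)
        net = ann.init_network(topo, np.random.default_rng(0))
        for W in net.weights:
            W[:] = 0.0
        for b in net.biases:
            b[:] = 0.0
        net.biases[-1][:] = [0.5, 0.5]
        assert ann.predict_class(net, np.zeros((1, 2)))[0] == 0


class TestTrainLM:
    def test_training_mse_never_increases(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        T = ann.one_hot((X[:, 0] > 0).astype(int), 2)
        topo = ann.NetworkTopology(1, 20, 2, 2)
        net = ann.init_network(topo, rng)
        trained = ann.train_lm(net, X, T, X[:5], T[:5], ann.TrainConfig(max_iter=40))
        hist = np.array(trained.train_mse_history)
        assert np.all(np.diff(hist) <= 1e-15)

    def test_separable_blobs_perfectly_classified_by_every_topology(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(8, 1, (30, 2))])
        y = np.repeat([0, 1], 30)
        T = ann.one_hot(y, 2)
        for topo in ann.build_topologies(2, 2):
            net = ann.init_network(topo, np.random.default_rng(5))
            trained = ann.train_lm(net, X, T, X[::5], T[::5], ann.TrainConfig(max_iter=100))
            assert (ann.predict_class(trained.network, X) != y).sum() == 0

    def test_lm_beats_long_gradient_descent_on_tiny_net(self):
        rng = np.random.default_rng(3)
        X = np.linspace(-1, 1, 5)[:, None]
        T = np.column_stack([X[:, 0] ** 2, -X[:, 0]])
        topo = ann.NetworkTopology(1, 20, 1, 2)
        start = ann.init_network(topo, np.random.default_rng(4))
        # 1-2-2 net: shrink by zeroing all but 2 hidden units is equivalent
        # to training the full net; instead compare on the same architecture
        trained = ann.train_lm(
            start, X, T, X, T, ann.TrainConfig(max_iter=200, max_val_fails=10**9)
        )
        # gradient-descent oracle, 5000 steps, same start
        gd = start.copy()
        lr = 0.05
        n_el = T.size
        for _ in range(5000):
            r = (ann.forward(gd, X) - T).ravel()
            grad = 2.0 * ann.jacobian(gd, X).T @ r / n_el
            gd.unpack(gd.pack() - lr * grad)
        gd_mse = float(np.mean((ann.forward(gd, X) - T) ** 2))
        assert trained.final_train_mse <= gd_mse + 1e-12

    def test_stop_reasons(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        T = ann.one_hot((X.sum(axis=1) > 0).astype(int), 2)
        topo = ann.NetworkTopology(1, 20, 2, 2)
        net = ann.init_network(topo, rng)
        # tiny iteration cap -> max_iter
        t1 = ann.train_lm(net, X, T, X[:4], T[:4], ann.TrainConfig(max_iter=2))
        assert t1.stop_reason == "max_iter" and t1.n_iterations == 2
        # separable memorization -> mse_floor reachable
        t2 = ann.train_lm(net, X, T, X[:4], T[:4], ann.TrainConfig(max_iter=500, max_val_fails=10**9))
        assert t2.stop_reason in ("mse_floor", "max_iter", "max_damping")
        # noise targets with tiny validation -> val_fails fires
        rng2 = np.random.default_rng(7)
        T_noise = ann.one_hot(rng2.integers(0, 2, 20), 2)
        V_noise = ann.one_hot(rng2.integers(0, 2, 8), 2)
        t3 = ann.train_lm(
            net, X, T_noise, rng2.normal(size=(8, 2)), V_noise,
            ann.TrainConfig(max_iter=500),
        )
        assert t3.stop_reason in ("val_fails", "mse_floor", "max_damping")

    def test_returned_weights_are_validation_minimum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        T = ann.one_hot((X[:, 0] > 0).astype(int), 2)
        Xv = rng.normal(size=(10, 3))
        Tv = ann.one_hot((Xv[:, 0] > 0).astype(int), 2)
        topo = ann.NetworkTopology(2, 20, 3, 2)
        net = ann.init_network(topo, rng)
        trained = ann.train_lm(net, X, T, Xv, Tv, ann.TrainConfig(max_iter=60))
        got = float(np.mean((ann.forward(trained.network, Xv) - Tv) ** 2))
        assert got == pytest.approx(trained.best_val_mse, rel=1e-9)
        assert trained.best_val_mse == pytest.approx(min(trained.val_mse_history), rel=1e-9)

    def test_seed_determinism_of_full_training(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(24, 2))
        T = ann.one_hot((X[:, 1] > 0).astype(int), 2)
        outs = []
        for _ in range(2):
            net = ann.init_network(ann.NetworkTopology(2, 20, 2, 2), np.random.default_rng(11))
            tr = ann.train_lm(net, X, T, X[:6], T[:6], ann.TrainConfig(max_iter=25))
            outs.append(tr.network.pack())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_high_damping_step_approaches_gradient_direction(self):
        # LM with lambda -> infinity reduces to a vanishing gradient step
        rng = np.random.default_rng(10)
        topo = ann.NetworkTopology(1, 20, 2, 2)
        net = ann.init_network(topo, rng)
        X = rng.normal(size=(10, 2))
        T = ann.one_hot((X[:, 0] > 0).astype(int), 2)
        r = (ann.forward(net, X) - T).ravel()
        J = ann.jacobian(net, X)
        lam = 1e12
        step = ann._lm_step(J, r, lam)
        expected = -(J.T @ r) / lam
        np.testing.assert_allclose(step, expected, rtol=1e-3)

    def test_empty_sets_rejected(self):
        topo = ann.NetworkTopology(1, 20, 2, 2)
        net = ann.init_network(topo, np.random.default_rng(0))
        with pytest.raises(ValueError):
            ann.train_lm(net, np.zeros((0, 2)), np.zeros((0, 2)), np.zeros((1, 2)), np.zeros((1, 2)))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        net = ann.init_network(ann.NetworkTopology(2, 50, 3, 4), np.random.default_rng(0))
        path = tmp_path / "net.json"
        net.to_json(path)
        back = ann.Network.from_json(path)
        assert back.topology == net.topology
        X = np.random.default_rng(1).normal(size=(6, 3))
        np.testing.assert_allclose(ann.forward(back, X), ann.forward(net, X))
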