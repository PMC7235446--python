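"""Unit tests for layer stacking, the online trainer and evaluation."""

import numpy as np
import pytest

from pydecolle import (
    LayerSpec,
    Metrics,
    NetworkSpec,
    TrainConfig,
    Trainer,
    apply_dropout,
    build_network,
    evaluate_classification,
    max_pool,
    train_online,
)
from pydecolle.neurons import NeuronConfig


def dense_spec(n_layers=3, n_units=16, n_in=10, n_targets=1):
    return NetworkSpec(
        input_shape=(n_in,),
        layers=[LayerSpec(kind="dense", n_units=n_units, n_targets=n_targets)
                for _ in range(n_layers)],
    )


def conv_spec(dropout=0.0):
    return NetworkSpec(
        input_shape=(2, 16, 16),
        layers=[
            LayerSpec(kind="conv", out_channels=4, kernel=5, padding=2,
                      pool=2, dropout=dropout, n_targets=4),
            LayerSpec(kind="conv", out_channels=6, kernel=3, padding=1,
                      pool=2, dropout=dropout, n_targets=4),
        ],
    )


def random_stream(T, B, shape, p=0.2, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.random((T, B, *shape)) < p).astype(float)


class TestBuildNetwork:
    def test_dense_stack_structure(self):
        net = build_network(dense_spec(), seed=0)
        assert len(net.layers) == 3
        for layer in net.layers:
            assert layer.W.shape == (16, layer.in_shape[0])
            assert np.all(layer.b == -0.01)
            assert layer.readout.G.shape == (1, 16)

    def test_weight_bounds_follow_fan_in(self):
        net = build_network(dense_spec(n_in=25), seed=0)
        assert np.all(np.abs(net.layers[0].W) <= 1 / np.sqrt(25))

    def test_conv_geometry_chain(self):
        """16x16 -> conv5 pad2 -> 16x16 -> pool -> 8x8 -> conv3 pad1 -> 8x8 -> pool -> 4x4."""
        net = build_network(conv_spec(), seed=0)
        assert net.layers[0].out_shape == (4, 8, 8)
        assert net.layers[1].out_shape == (6, 4, 4)

    def test_table_architecture_dimensions(self):
        """The event-vision stack template: 32x32 input, 7x7 kernels with
        padding 2, pools of 2, 2, 1 gives maps 15x15, 13x13 ... and 5x5 after
        the final 2x2 pool."""
        spec = NetworkSpec(
            input_shape=(2, 32, 32),
            layers=[
                LayerSpec(kind="conv", out_channels=4, kernel=7, padding=2, pool=2),
                LayerSpec(kind="conv", out_channels=4, kernel=7, padding=2, pool=1),
                LayerSpec(kind="conv", out_channels=4, kernel=7, padding=2, pool=2),
            ],
        )
        net = build_network(spec, seed=0)
        assert net.layers[0].out_shape[1:] == (15, 15)
        assert net.layers[1].out_shape[1:] == (13, 13)
        assert net.layers[2].out_shape[1:] == (5, 5)

    def test_deterministic_given_seed(self):
        a = build_network(dense_spec(), seed=3)
        b = build_network(dense_spec(), seed=3)
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.W, lb.W)
            assert np.array_equal(la.readout.G, lb.readout.G)
            assert np.array_equal(la.readout.H, lb.readout.H)

    def test_bad_geometry_reports_layer_index(self):
        spec = NetworkSpec(
            input_shape=(2, 4, 4),
            layers=[LayerSpec(kind="conv", out_channels=2, kernel=7, padding=0)],
        )
        with pytest.raises(ValueError, match="layer 0"):
            build_network(spec, seed=0)


class TestForwardStep:
    def test_silent_input_silent_network(self):
        net = build_network(dense_spec(), seed=1)
        states = net.init_states(2)
        states, outs = net.forward_step(states, np.zeros((2, 10)))
        for out in outs:
            assert not out["S"].any() and not out["Y"].any()

    def test_single_layer_matches_step_layer_plus_readout(self):
        from pydecolle import local_readout, step_layer

        net = build_network(dense_spec(n_layers=1), seed=2)
        layer = net.layers[0]
        frame = random_stream(1, 3, (10,), seed=5)[0]
        states = net.init_states(3)
        _, outs = net.forward_step(states, frame)
        ref_state, ref_S = step_layer(net.init_states(3)[0], frame, layer.W,
                                      layer.b, NeuronConfig())
        assert np.array_equal(outs[0]["S"], ref_S)
        np.testing.assert_allclose(outs[0]["Y"],
                                   local_readout(ref_S, layer.readout.G))

    def test_state_size_independent_of_history(self):
        net = build_network(dense_spec(), seed=0)
        stream = random_stream(60, 1, (10,), seed=1)
        states = net.init_states(1)
        sizes = []
        for t in range(60):
            states, _ = net.forward_step(states, stream[t])
            sizes.append(net.state_scalars(states))
        assert len(set(sizes)) == 1


class TestDropout:
    def test_p_zero_identity(self):
        x = np.ones((4, 10))
        out, mask = apply_dropout(x, 0.0, "train", 0)
        assert np.array_equal(out, x) and np.all(mask == 1)

    def test_eval_mode_identity(self):
        x = np.ones((4, 10))
        out, _ = apply_dropout(x, 0.5, "eval", 0)
        assert np.array_equal(out, x)

    def test_keep_rate_and_scaling(self):
        n = 100_000
        x = np.ones((1, n))
        out, _ = apply_dropout(x, 0.5, "train", np.random.default_rng(0))
        keep = (out != 0).mean()
        assert abs(keep - 0.5) < 3 * np.sqrt(0.25 / n)
        assert out.max() == pytest.approx(2.0)  # survivors scaled by 1/(1-p)
        assert out.mean() == pytest.approx(1.0, abs=0.02)  # expectation preserved

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            apply_dropout(np.ones(3), 1.0, "train", 0)


class TestMaxPool:
    def test_window_max(self):
        assert max_pool(np.array([[1.0, 2.0], [3.0, 4.0]]))[0, 0] == 4.0

    def test_constant_map(self):
        out = max_pool(np.full((1, 1, 6, 6), 2.5))
        assert out.shape == (1, 1, 3, 3) and np.all(out == 2.5)

    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(2, 3, 6, 6))
        out = max_pool(m)
        for y in range(3):
            for x in range(3):
                ref = m[..., 2 * y:2 * y + 2, 2 * x:2 * x + 2].max(axis=(-2, -1))
                np.testing.assert_array_equal(out[..., y, x], ref)

    def test_odd_dims_truncated(self):
        assert max_pool(np.zeros((1, 5, 7))).shape == (1, 2, 3)


class TestTrainOnline:
    def _setup(self, T=40, B=2, eta=1e-3, burn_in=0.0):
        net = build_network(dense_spec(), seed=4)
        cfg = TrainConfig(eta=eta, burn_in=burn_in)
        stream = random_stream(T, B, (10,), seed=9)
        rng = np.random.default_rng(1)
        targets = [rng.uniform(0, 1, size=(T, 1)) for _ in range(3)]
        return net, cfg, stream, targets

    def test_eta_zero_leaves_weights_and_logs_metrics(self):
        net, cfg, stream, targets = self._setup(eta=0.0)
        before = [layer.W.copy() for layer in net.layers]
        metrics = train_online(net, stream, targets, cfg)
        for w0, layer in zip(before, net.layers):
            assert np.array_equal(w0, layer.W)
        assert metrics.n_updates == 40
        assert len(metrics.records) > 0

    def test_full_burn_in_means_no_updates(self):
        net, cfg, stream, targets = self._setup(T=40, burn_in=40.0)
        before = [layer.W.copy() for layer in net.layers]
        metrics = train_online(net, stream, targets, cfg)
        assert metrics.n_updates == 0
        for w0, layer in zip(before, net.layers):
            assert np.array_equal(w0, layer.W)

    def test_burn_in_update_count(self):
        """A 300-step sequence with 50 ms burn-in at 1 ms steps gives exactly
        250 update steps."""
        net = build_network(dense_spec(), seed=4)
        cfg = TrainConfig(eta=1e-4, burn_in=50.0)
        stream = random_stream(300, 1, (10,), seed=2)
        targets = [np.zeros((300, 1))] * 3
        metrics = train_online(net, stream, targets, cfg)
        assert metrics.n_updates == 250

    def test_misaligned_targets_rejected(self):
        net, cfg, stream, targets = self._setup(T=40)
        bad = [t[:-3] for t in targets]
        with pytest.raises(ValueError):
            train_online(net, stream, bad, cfg)

    def test_readouts_fixed_through_training(self):
        net, cfg, stream, targets = self._setup()
        G0 = [layer.readout.G.copy() for layer in net.layers]
        H0 = [layer.readout.H.copy() for layer in net.layers]
        train_online(net, stream, targets, cfg)
        for layer, g0, h0 in zip(net.layers, G0, H0):
            assert np.array_equal(layer.readout.G, g0)
            assert np.array_equal(layer.readout.H, h0)

    def test_layerwise_locality(self):
        """Perturbing layer 3's weights leaves layers 1-2 updates bit-identical."""
        results = []
        for perturb in (False, True):
            net, cfg, stream, targets = self._setup(T=20)
            if perturb:
                net.layers[2].W = np.zeros_like(net.layers[2].W)
            train_online(net, stream, targets, cfg)
            results.append([net.layers[i].W.copy() for i in range(3)])
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])

    def test_memory_constancy_across_sequence_lengths(self):
        """Persistent scalar training state is identical for 100- and
        10000-step sequences (streaming rule, no stored history)."""
        sizes = []
        for T in (100, 10_000):
            net = build_network(dense_spec(n_layers=2, n_units=8), seed=0)
            cfg = TrainConfig(eta=1e-4)
            trainer = Trainer(net, cfg)
            stream = random_stream(T, 1, (10,), seed=3)
            targets = [np.zeros((T, 1))] * 2
            m = trainer.train_sequence(stream, targets)
            sizes.append(m.state_scalars)
        assert sizes[0] == sizes[1]

    def test_learning_rate_schedule(self):
        net = build_network(dense_spec(n_layers=1, n_units=4), seed=0)
        cfg = TrainConfig(eta=1.0, lr_divisor=10.0, lr_interval=5)
        trainer = Trainer(net, cfg)
        assert trainer.eta == 1.0
        trainer.update_count = 5
        assert trainer.eta == pytest.approx(0.1)
        trainer.update_count = 12
        assert trainer.eta == pytest.approx(0.01)


class TestEvaluateClassification:
    def test_forced_one_hot_readout(self):
        """A readout forced to favour one class predicts that class."""
        net = build_network(dense_spec(n_layers=1, n_units=8, n_targets=4), seed=1)
        G = np.zeros((4, 8))
        G[2] = 1.0  # any spike activity votes for class 2
        net.layers[0].readout.G = G
        stream = random_stream(30, 5, (10,), p=0.6, seed=0)
        preds = evaluate_classification(net, stream, TrainConfig())
        assert np.all(preds[0] == 2)

    def test_tie_breaks_to_lowest_index(self):
        net = build_network(dense_spec(n_layers=1, n_units=8, n_targets=6), seed=1)
        net.layers[0].readout.G = np.zeros((6, 8))  # all-zero readout: 6-way tie
        stream = random_stream(20, 3, (10,), seed=1)
        preds = evaluate_classification(net, stream, TrainConfig())
        assert np.all(preds[0] == 0)

    def test_accumulated_argmax_matches_explicit_loop(self):
        net = build_network(dense_spec(n_layers=2, n_units=8, n_targets=3), seed=2)
        stream = random_stream(25, 4, (10,), p=0.5, seed=7)
        cfg = TrainConfig(burn_in=5.0)
        preds = evaluate_classification(net, stream, cfg)
        # explicit recomputation
        states = net.init_states(4)
        acc = [np.zeros((4, 3)) for _ in net.layers]
        for t in range(25):
            states, outs = net.forward_step(states, stream[t])
            if t >= 5:
                for li, out in enumerate(outs):
                    acc[li] += out["Y"]
        for li in range(2):
            assert np.array_equal(preds[li], acc[li].argmax(axis=1))

    def test_stream_shorter_than_burn_in_rejected(self):
        net = build_network(dense_spec(n_layers=1, n_units=4), seed=0)
        stream = random_stream(10, 1, (10,))
        with pytest.raises(ValueError):
            evaluate_classification(net, stream, TrainConfig(burn_in=20.0))

    def test_spike_count_mode(self):
        net = build_network(dense_spec(n_layers=1, n_units=4, n_targets=4), seed=3)
        stream = random_stream(15, 2, (10,), p=0.8, seed=4)
        preds = evaluate_classification(net, stream, TrainConfig(), mode="spikes")
        assert preds.shape == (1, 2)
        assert np.all((preds[-1] >= 0) & (preds[-1] < 4))


class TestMetrics:
    def test_csv_round_trip(self, tmp_path):
        m = Metrics()
        m.log(0, 0, 0.5, 0.01, 0.2)
        m.log(1, 1, 0.4, 0.02, 0.3)
        path = tmp_path / "metrics.csv"
        m.to_csv(path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "step,layer,loss,reg,spike_rate"
        assert len(lines) == 3
        assert np.array_equal(m.layer_losses(0), [0.5])
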