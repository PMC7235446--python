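"""Runnable experiments: the regression probe task and the synthetic
moving-bar classification task, plus checkpoint plumbing.

The regression task follows the classic demonstration of layerwise local
learning: a stack of fully connected spiking layers is driven by one fixed
Poisson spike train, and each layer's one-dimensional random readout is
regressed onto its own pseudo-target (a ramp, a fast sinusoid, a slow
sinusoid).  The classification task is an explicit synthetic stand-in for
event-camera gesture recognition: bars sweep across a small two-polarity
sensor in class-dependent directions and a convolutional stack with pooling
and dropout is trained online with per-layer readouts.
"""

from __future__ import annotations

import hashlib
import os

import numpy as np

from .config import DataConfig, ExperimentConfig, save_config
from .data import bin_events, moving_bar_events, poisson_spike_train, regression_targets
from .network import (
    LayerSpec,
    Metrics,
    Network,
    NetworkSpec,
    TrainConfig,
    Trainer,
    build_network,
    evaluate_classification,
)

__all__ = [
    "default_regression_config",
    "default_classification_config",
    "run_regression",
    "run_classification",
    "make_classification_set",
    "save_checkpoint",
    "load_checkpoint",
    "inspect_checkpoint",
]


def default_regression_config(n_units: int = 64, seed: int = 1,
                              out_dir: str = "scratch/regression") -> ExperimentConfig:
    """Three fully connected layers, one readout target each."""
    return ExperimentConfig(
        task="regression",
        seed=seed,
        out_dir=out_dir,
        n_passes=200,
        batch_size=1,
        train=TrainConfig(eta=1e-4, loss="mse", burn_in=0.0,
                          lambda1=0.05, lambda2=0.05),
        data=DataConfig(n_inputs=100, rate_hz=50.0, duration_ms=500.0),
        layers=[LayerSpec(kind="dense", n_units=n_units, n_targets=1)
                for _ in range(3)],
    )


def default_classification_config(seed: int = 1,
                                  out_dir: str = "scratch/classify") -> ExperimentConfig:
    """Two conv layers with 2x2 pooling and dropout on a 16x16 sensor."""
    return ExperimentConfig(
        task="classification",
        seed=seed,
        out_dir=out_dir,
        n_passes=6,  # epochs over the training set
        batch_size=16,
        train=TrainConfig(eta=1e-3, loss="smooth_l1", burn_in=50.0,
                          lambda1=0.05, lambda2=0.05,
                          lr_divisor=5.0, lr_interval=1500),
        data=DataConfig(n_classes=4, width=16, height=16, duration_ms=300.0,
                        speed=1.0, bar_width=2, jitter=0.25, noise_rate=1.0,
                        n_train=32, n_test=100),
        layers=[
            LayerSpec(kind="conv", out_channels=8, kernel=5, padding=2,
                      pool=2, dropout=0.5, n_targets=4),
            LayerSpec(kind="conv", out_channels=16, kernel=3, padding=1,
                      pool=2, dropout=0.5, n_targets=4),
        ],
    )


def _network_spec(cfg: ExperimentConfig) -> NetworkSpec:
    if cfg.task == "regression":
        input_shape = (cfg.data.n_inputs,)
    else:
        input_shape = (2, cfg.data.height, cfg.data.width)
    return NetworkSpec(input_shape=input_shape, layers=cfg.layers, neuron=cfg.neuron)


def run_regression(cfg: ExperimentConfig, write_outputs: bool = True):
    """Train the regression stack on a fixed Poisson stimulus.

    Returns (results dict, metrics, network).  The results carry the
    per-layer readout loss before and after training, both evaluated with
    frozen weights on the training stimulus.
    """
    if cfg.task != "regression":
        raise ValueError(f"config is for task {cfg.task!r}")
    if not cfg.layers:
        raise ValueError("config has no layers")
    T = int(round(cfg.data.duration_ms / cfg.neuron.dt))
    stim = poisson_spike_train(np.full(cfg.data.n_inputs, cfg.data.rate_hz),
                               T, cfg.neuron.dt, seed=cfg.seed)
    frames = stim[:, None, :]  # (T, 1, n_inputs)
    traces = regression_targets(T, cfg.neuron.dt, cfg.data.f_hi, cfg.data.f_lo)
    targets = [traces[:, [li % 3]] for li in range(len(cfg.layers))]

    net = build_network(_network_spec(cfg), cfg.seed)
    trainer = Trainer(net, cfg.train)
    initial = trainer.evaluate_losses(frames, targets)
    w0 = [layer.W.copy() for layer in net.layers]
    metrics = Metrics()
    for _ in range(cfg.n_passes):
        trainer.train_sequence(frames, targets, metrics=metrics)
    final = trainer.evaluate_losses(frames, targets)
    results = {
        "initial_loss": initial.tolist(),
        "final_loss": final.tolist(),
        "loss_ratio": (initial / np.maximum(final, 1e-300)).tolist(),
        "n_updates": metrics.n_updates,
        "weights_changed": [not np.array_equal(w0[i], net.layers[i].W)
                            for i in range(len(net.layers))],
    }
    if write_outputs:
        _write_outputs(cfg, net, trainer, metrics)
    return results, metrics, net


def make_classification_set(data: DataConfig, n_seq: int, dt: float, seed: int):
    """Generate (frames, labels): frames (n_seq, T, 2, H, W), balanced classes."""
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(n_seq)
    labels = np.arange(n_seq) % data.n_classes
    frames = np.stack([
        bin_events(moving_bar_events(
            int(labels[i]), data.width, data.height, data.duration_ms, dt,
            data.speed, data.bar_width, data.jitter, data.noise_rate,
            seed=int(seeds[i])), bin_ms=dt)
        for i in range(n_seq)
    ])
    return frames.astype(float), labels


def run_classification(cfg: ExperimentConfig, write_outputs: bool = True):
    """Train the conv stack on the moving-bar task and report test errors.

    Returns (results dict, metrics, network).  Test error is reported per
    layer, with dropout off and (per the event-camera convention of keeping
    dropout active at test time) on.
    """
    if cfg.task != "classification":
        raise ValueError(f"config is for task {cfg.task!r}")
    d = cfg.data
    dt = cfg.neuron.dt
    train_x, train_y = make_classification_set(d, d.n_train, dt, cfg.seed)
    test_x, test_y = make_classification_set(d, d.n_test, dt, cfg.seed + 10_000)

    net = build_network(_network_spec(cfg), cfg.seed)
    trainer = Trainer(net, cfg.train)
    metrics = Metrics()
    order_rng = np.random.default_rng(cfg.seed + 1)
    n_layers = len(net.layers)
    T = train_x.shape[1]
    for _ in range(cfg.n_passes):
        order = order_rng.permutation(d.n_train)
        for start in range(0, d.n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = np.moveaxis(train_x[idx], 0, 1)  # (T, B, 2, H, W)
            onehot = np.eye(d.n_classes)[train_y[idx]]
            tgt = np.broadcast_to(onehot, (T, *onehot.shape))
            trainer.train_sequence(batch, [tgt] * n_layers, metrics=metrics)

    stream = np.moveaxis(test_x, 0, 1)
    results = {"n_updates": metrics.n_updates}
    for label, active in (("test_error", False), ("test_error_dropout", True)):
        eval_cfg = TrainConfig(**{**cfg.train.__dict__, "dropout_active_at_eval": active})
        preds = evaluate_classification(net, stream, eval_cfg, mode="readout")
        results[label] = [float(np.mean(preds[li] != test_y))
                          for li in range(n_layers)]
    results["test_accuracy"] = [1.0 - e for e in results["test_error"]]
    if write_outputs:
        _write_outputs(cfg, net, trainer, metrics)
    return results, metrics, net


def _write_outputs(cfg: ExperimentConfig, net: Network, trainer: Trainer,
                   metrics: Metrics) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)
    save_config(cfg, os.path.join(cfg.out_dir, "config.yaml"))
    metrics.to_csv(os.path.join(cfg.out_dir, "metrics.csv"))
    save_checkpoint(os.path.join(cfg.out_dir, "checkpoint.npz"), net, trainer, cfg)


def save_checkpoint(path, net: Network, trainer: Trainer | None = None,
                    cfg: ExperimentConfig | None = None) -> None:
    """Single-archive checkpoint: weights, readouts, optimizer state, config hash."""
    arrays = {}
    for i, layer in enumerate(net.layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
        arrays[f"G{i}"] = layer.readout.G
        arrays[f"H{i}"] = layer.readout.H
        if trainer is not None:
            st = trainer.opt_states[i]
            for j, name in enumerate(("W", "b")):
                arrays[f"m_{name}{i}"] = st.m[j]
                arrays[f"u_{name}{i}"] = st.u[j]
            arrays[f"opt_t{i}"] = np.array(st.t)
    arrays["n_layers"] = np.array(len(net.layers))
    if cfg is not None:
        text = cfg.to_yaml()
        arrays["config_yaml"] = np.array(text)
        arrays["config_sha256"] = np.array(hashlib.sha256(text.encode()).hexdigest())
    np.savez(path, **arrays)


def load_checkpoint(path) -> dict:
    """Load a checkpoint archive back into a plain dict of arrays."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no checkpoint at {path}")
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:  # zipfile/format errors
        raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
    if "n_layers" not in data:
        raise ValueError(f"corrupt checkpoint {path}: missing layer count")
    return data


def inspect_checkpoint(path) -> str:
    """Human-readable summary: geometries, parameter counts, kernel stats."""
    data = load_checkpoint(path)
    n_layers = int(data["n_layers"])
    lines = [f"checkpoint: {path}", f"layers: {n_layers}"]
    total = 0
    for i in range(n_layers):
        W, b, G = data[f"W{i}"], data[f"b{i}"], data[f"G{i}"]
        n = W.size + b.size
        total += n
        lines.append(
            f"  layer {i}: W{tuple(W.shape)} b{tuple(b.shape)} "
            f"readout G{tuple(G.shape)} | {n} trainable params | "
            f"|W| mean {np.abs(W).mean():.4g} max {np.abs(W).max():.4g}")
    lines.append(f"total trainable parameters: {total}")
    W0 = data["W0"]
    if W0.ndim == 4:
        lines.append(
            f"first-layer kernels: {W0.shape[0]} x {W0.shape[1]} channels, "
            f"{W0.shape[2]}x{W0.shape[3]}; per-kernel mean range "
            f"[{W0.mean(axis=(1, 2, 3)).min():.4g}, {W0.mean(axis=(1, 2, 3)).max():.4g}]")
    if "config_sha256" in data:
        lines.append(f"config sha256: {str(data['config_sha256'])}")
    return "\n".join(lines)
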