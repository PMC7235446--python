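"""Layer stacking and the online per-timestep training loop.

A network is an ordered stack of spiking layers (dense or convolutional, the
latter optionally followed by 2x2 max-pooling on the membrane map and dropout
on the spike output).  Spikes are passed forward as values only; every layer
owns a fixed random readout and is trained against its own pseudo-target, so
no error information ever crosses a layer boundary.  Updates are applied at
every simulation timestep after an initial burn-in during which the states
equilibrate.  The persistent training state is the forward state plus the
optimizer accumulators — nothing scales with the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learning import (
    AdaMaxState,
    ReadoutConfig,
    adamax_init,
    adamax_step,
    backproject_error,
    im2col,
    local_readout,
    loss_and_error,
    regularizer,
    surrogate_derivative,
)
from .neurons import (
    LayerState,
    NeuronConfig,
    heaviside,
    update_refractory,
    update_traces,
)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "Metrics",
    "Network",
    "Trainer",
    "build_network",
    "forward_step",
    "train_online",
    "evaluate_classification",
    "apply_dropout",
    "max_pool",
]


@dataclass
class LayerSpec:
    """Geometry of one spiking layer.

    ``kind`` is ``dense`` (``n_units``) or ``conv`` (``out_channels`` /
    ``kernel`` / ``padding``, stride 1).  ``pool`` of 2 applies 2x2 max-pooling
    to the membrane map before thresholding; ``dropout`` masks the spike
    output (inverted dropout).  ``n_targets`` sizes the layer's local readout.
    """

    kind: str = "dense"
    n_units: int | None = None
    out_channels: int | None = None
    kernel: int = 7
    padding: int = 0
    pool: int = 1
    dropout: float = 0.0
    n_targets: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("dense", "conv"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.kind == "dense" and not self.n_units:
            raise ValueError("dense layer needs n_units")
        if self.kind == "conv" and not self.out_channels:
            raise ValueError("conv layer needs out_channels")


@dataclass
class NetworkSpec:
    """Input geometry plus ordered layer descriptors and the neuron config."""

    input_shape: tuple  # (n_in,) for dense input, (C, H, W) for frames
    layers: list = field(default_factory=list)
    neuron: NeuronConfig = field(default_factory=NeuronConfig)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("network needs at least one layer")
        self.input_shape = tuple(self.input_shape)


def apply_dropout(spikes, p: float, mode: str = "train", rng=None):
    """Inverted dropout on spike values.

    In ``train`` mode each unit is zeroed independently with probability p and
    survivors are scaled by 1/(1-p); in ``eval`` mode this is the identity.
    Returns (masked spikes, mask) where the mask already includes the scale.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout probability must be in [0, 1), got {p}")
    spikes = np.asarray(spikes, dtype=float)
    if p == 0.0 or mode == "eval":
        return spikes, np.ones_like(spikes)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask = (rng.random(spikes.shape) >= p) / (1.0 - p)
    return spikes * mask, mask


def max_pool(U_map: np.ndarray, window: int = 2) -> np.ndarray:
    """Non-overlapping window max over the trailing two (spatial) axes.

    Odd trailing dimensions are truncated.  Applied to the membrane map before
    thresholding (conv -> pool -> spiking nonlinearity).
    """
    pooled, _ = _max_pool_argmax(np.asarray(U_map, dtype=float), window)
    return pooled


def _pool_view(M: np.ndarray, w: int):
    H, W = M.shape[-2], M.shape[-1]
    Ho, Wo = H // w, W // w
    v = M[..., :Ho * w, :Wo * w]
    v = v.reshape(*M.shape[:-2], Ho, w, Wo, w)
    v = np.moveaxis(v, -3, -2)  # (..., Ho, Wo, w, w)
    return v.reshape(*v.shape[:-2], w * w)


def _max_pool_argmax(M: np.ndarray, w: int):
    if w == 1:
        return M, None
    v = _pool_view(M, w)
    idx = v.argmax(axis=-1)
    return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0], idx


def _pool_scatter(delta: np.ndarray, idx, shape, w: int) -> np.ndarray:
    """Route pooled-resolution deltas back to the argmax pre-pool positions."""
    if w == 1:
        return delta
    Ho, Wo = delta.shape[-2], delta.shape[-1]
    out = np.zeros(shape[:-2] + (Ho, w, Wo, w), dtype=float)
    v = np.moveaxis(out, -3, -2).reshape(*delta.shape, w * w)
    np.put_along_axis(v, idx[..., None], delta[..., None], axis=-1)
    full = np.zeros(shape, dtype=float)
    full[..., :Ho * w, :Wo * w] = np.moveaxis(
        v.reshape(*delta.shape, w, w), -2, -3).reshape(*delta.shape[:-2], Ho * w, Wo * w)
    return full


class _DenseDecolleLayer:
    """Fully connected spiking layer with a fixed local readout."""

    kind = "dense"

    def __init__(self, n_in: int, spec: LayerSpec, neuron: NeuronConfig,
                 readout: ReadoutConfig, seed: int):
        rng = np.random.default_rng(seed)
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(spec.n_units, n_in))
        self.b = np.full(spec.n_units, -0.01)
        self.readout = readout
        self.neuron = neuron
        self.spec = spec
        self.in_shape = (n_in,)
        self.out_shape = (spec.n_units,)
        self.n_out = spec.n_units
        self.dropout_rng = np.random.default_rng([seed, 7])

    def init_state(self, batch: int) -> LayerState:
        z_in = np.zeros((batch, self.in_shape[0]))
        z_out = np.zeros((batch, self.n_out))
        return LayerState(P=z_in, Q=z_in.copy(), R=z_out, U=z_out.copy(), S=z_out.copy())

    def step(self, state: LayerState, S_in: np.ndarray):
        S_in = S_in.reshape(S_in.shape[0], -1)
        P, Q = update_traces(state.P, state.Q, S_in, self.neuron.alpha, self.neuron.beta)
        U = P @ self.W.T - self.neuron.rho * state.R + self.b
        S = heaviside(U)
        R = update_refractory(state.R, S, self.neuron.gamma)
        return LayerState(P=P, Q=Q, R=R, U=U, S=S), {}

    def gradients(self, delta: np.ndarray, state: LayerState, aux):
        B = delta.shape[0]
        gW = delta.T @ state.P / B
        gb = delta.mean(axis=0)
        return [gW, gb]

    @property
    def params(self):
        return [self.W, self.b]

    @params.setter
    def params(self, new):
        self.W, self.b = new

    @property
    def n_param_scalars(self) -> int:
        return self.W.size + self.b.size


class _ConvDecolleLayer:
    """Convolutional spiking layer (stride 1) with optional membrane pooling.

    The convolution acts on the P traces of the input channels; the membrane
    map is max-pooled before thresholding, so the layer's neurons live at the
    pooled resolution (refractory state included).
    """

    kind = "conv"

    def __init__(self, in_shape: tuple, spec: LayerSpec, neuron: NeuronConfig,
                 readout: ReadoutConfig, seed: int):
        C_in, H, W = in_shape
        k, pad = spec.kernel, spec.padding
        self.conv_hw = (H + 2 * pad - k + 1, W + 2 * pad - k + 1)
        if min(self.conv_hw) < 1:
            raise ValueError(f"kernel {k} too large for input {in_shape} with padding {pad}")
        self.pool = spec.pool
        out_hw = (self.conv_hw[0] // self.pool, self.conv_hw[1] // self.pool)
        rng = np.random.default_rng(seed)
        fan_in = C_in * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(spec.out_channels, C_in, k, k))
        self.b = np.full(spec.out_channels, -0.01)
        self.readout = readout
        self.neuron = neuron
        self.spec = spec
        self.in_shape = in_shape
        self.out_shape = (spec.out_channels, *out_hw)
        self.n_out = int(np.prod(self.out_shape))
        self.dropout_rng = np.random.default_rng([seed, 7])

    def init_state(self, batch: int) -> LayerState:
        z_in = np.zeros((batch, *self.in_shape))
        z_out = np.zeros((batch, *self.out_shape))
        return LayerState(P=z_in, Q=z_in.copy(), R=z_out, U=z_out.copy(), S=z_out.copy())

    def step(self, state: LayerState, S_in: np.ndarray):
        S_in = S_in.reshape(state.P.shape)
        P, Q = update_traces(state.P, state.Q, S_in, self.neuron.alpha, self.neuron.beta)
        C_out, C_in, k, _ = self.W.shape
        patches = im2col(P, k, k, self.spec.padding)  # (B, pos, C_in*k*k)
        M = patches @ self.W.reshape(C_out, -1).T + self.b  # (B, pos, C_out)
        B = M.shape[0]
        M = M.transpose(0, 2, 1).reshape(B, C_out, *self.conv_hw)
        pooled, idx = _max_pool_argmax(M, self.pool)
        U = pooled - self.neuron.rho * state.R
        S = heaviside(U)
        R = update_refractory(state.R, S, self.neuron.gamma)
        return (LayerState(P=P, Q=Q, R=R, U=U, S=S),
                {"patches": patches, "pool_idx": idx})

    def gradients(self, delta: np.ndarray, state: LayerState, aux):
        B = delta.shape[0]
        C_out = self.W.shape[0]
        pre = _pool_scatter(delta, aux["pool_idx"],
                            (B, C_out, *self.conv_hw), self.pool)
        d = pre.reshape(B, C_out, -1)
        gW = np.einsum("bcp,bpk->ck", d, aux["patches"]) / B
        gb = d.sum(axis=2).mean(axis=0)
        return [gW.reshape(self.W.shape), gb]

    @property
    def params(self):
        return [self.W, self.b]

    @params.setter
    def params(self, new):
        self.W, self.b = new

    @property
    def n_param_scalars(self) -> int:
        return self.W.size + self.b.size


class Network:
    """Ordered stack of spiking layers with per-layer fixed readouts."""

    def __init__(self, layers: list, spec: NetworkSpec):
        self.layers = layers
        self.spec = spec

    def init_states(self, batch: int) -> list:
        return [layer.init_state(batch) for layer in self.layers]

    def forward_step(self, states: list, frame: np.ndarray, dropout_on: bool = False):
        """Advance every layer by one timestep.

        The frame feeds layer 0; each subsequent layer receives the previous
        layer's (dropout-masked) spikes.  Returns the new states and one dict
        per layer with the spikes S (masked), membrane U, readout Y, the
        dropout mask and transient aux needed for same-step gradients.
        """
        S = np.asarray(frame, dtype=float)
        if S.shape[1:] != self.spec.input_shape:
            raise ValueError(f"frame shape {S.shape[1:]} != input {self.spec.input_shape}")
        new_states, outs = [], []
        for layer in self.layers:
            st, aux = layer.step(states[len(new_states)], S)
            mode = "train" if dropout_on else "eval"
            S_masked, mask = apply_dropout(st.S, layer.spec.dropout, mode, layer.dropout_rng)
            Y = local_readout(S_masked.reshape(S_masked.shape[0], -1), layer.readout.G)
            new_states.append(st)
            outs.append({"S": S_masked, "U": st.U, "Y": Y, "mask": mask, "aux": aux})
            S = S_masked
        return new_states, outs

    @property
    def n_param_scalars(self) -> int:
        return sum(l.n_param_scalars for l in self.layers)

    @property
    def n_readout_scalars(self) -> int:
        return sum(l.readout.G.size + l.readout.H.size for l in self.layers)

    def state_scalars(self, states: list) -> int:
        return sum(s.n_scalars for s in states)


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Construct a network with deterministic per-layer substreams of ``seed``.

    Weights are uniform +-1/sqrt(fan_in), biases -0.01 (resting membranes sit
    just under threshold, inside the boxcar window); each layer's G and H are
    drawn from derived seeds and fixed.
    """
    layers = []
    shape = spec.input_shape
    for i, lspec in enumerate(spec.layers):
        w_seed = np.random.SeedSequence([seed, i, 0]).generate_state(1)[0]
        g_seed = np.random.SeedSequence([seed, i, 1]).generate_state(1)[0]
        try:
            if lspec.kind == "dense":
                n_in = int(np.prod(shape))
                readout = ReadoutConfig.create(lspec.n_units, lspec.n_targets, int(g_seed))
                layer = _DenseDecolleLayer(n_in, lspec, spec.neuron, readout, int(w_seed))
            else:
                if len(shape) != 3:
                    raise ValueError(f"conv layer needs (C, H, W) input, got {shape}")
                layer = _ConvDecolleLayer(shape, lspec, spec.neuron,
                                          ReadoutConfig.create(1, 1, 0), int(w_seed))
                # readout size depends on the pooled output geometry
                layer.readout = ReadoutConfig.create(layer.n_out, lspec.n_targets, int(g_seed))
        except ValueError as exc:
            raise ValueError(f"layer {i}: {exc}") from exc
        layers.append(layer)
        shape = layer.out_shape
    return Network(layers, spec)


@dataclass
class TrainConfig:
    """Hyperparameters of the online training loop.

    ``burn_in`` is in ms (no updates while t < burn_in); the learning rate is
    divided by ``lr_divisor`` every ``lr_interval`` optimizer steps.
    """

    eta: float = 1e-4
    beta1: float = 0.0
    beta2: float = 0.95
    eps: float = 1e-8
    burn_in: float = 0.0
    lr_divisor: float = 1.0
    lr_interval: int = 500
    lambda1: float = 0.05
    lambda2: float = 0.05
    loss: str = "mse"
    dropout_active_at_eval: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.lr_divisor < 1 or self.lr_interval < 1:
            raise ValueError("schedule needs divisor >= 1 and interval >= 1")


@dataclass
class Metrics:
    """Per-layer loss traces and counters logged by the trainer."""

    records: list = field(default_factory=list)
    n_updates: int = 0
    state_scalars: int = 0

    def log(self, step: int, layer: int, loss: float, reg: float, spike_rate: float) -> None:
        self.records.append({"step": step, "layer": layer, "loss": loss,
                             "reg": reg, "spike_rate": spike_rate})

    def layer_losses(self, layer: int) -> np.ndarray:
        return np.array([r["loss"] for r in self.records if r["layer"] == layer])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step,layer,loss,reg,spike_rate\n")
            for r in self.records:
                fh.write(f"{r['step']},{r['layer']},{r['loss']:.10g},"
                         f"{r['reg']:.10g},{r['spike_rate']:.10g}\n")


class Trainer:
    """Online DECOLLE trainer: per-timestep three-factor updates per layer."""

    def __init__(self, net: Network, cfg: TrainConfig):
        self.net = net
        self.cfg = cfg
        self.opt_states = [adamax_init(layer.params) for layer in net.layers]
        self.update_count = 0

    @property
    def eta(self) -> float:
        drops = self.update_count // self.cfg.lr_interval
        return self.cfg.eta / (self.cfg.lr_divisor ** drops)

    def state_scalars(self, states: list) -> int:
        """Persistent training-state footprint in scalars (audit)."""
        return (self.net.state_scalars(states)
                + sum(s.n_scalars for s in self.opt_states)
                + self.net.n_param_scalars
                + self.net.n_readout_scalars)

    def train_sequence(self, frames: np.ndarray, targets: list,
                       metrics: Metrics | None = None, log_every: int = 50) -> Metrics:
        """Run one sequence (T, B, ...), updating every step after burn-in.

        ``targets`` is one array per layer, (T, n_targets) or (T, B,
        n_targets).  States are freshly initialized (and therefore reset
        between sequences); burn-in re-equilibrates them.
        """
        cfg, net = self.cfg, self.net
        T, B = frames.shape[0], frames.shape[1]
        for tgt in targets:
            if tgt.shape[0] != T:
                raise ValueError("target length does not match sequence length")
        states = net.init_states(B)
        metrics = metrics if metrics is not None else Metrics()
        burn_steps = int(round(cfg.burn_in / net.spec.neuron.dt))
        for t in range(T):
            states, outs = net.forward_step(states, frames[t], dropout_on=True)
            if t < burn_steps:
                continue
            eta = self.eta
            for li, (layer, out) in enumerate(zip(net.layers, outs)):
                tgt = targets[li][t]
                tgt = np.broadcast_to(tgt, out["Y"].shape)
                loss, dLdY = loss_and_error(out["Y"], tgt, cfg.loss)
                err = backproject_error(dLdY, layer.readout.H)
                err = err * out["mask"].reshape(B, -1)
                reg, dReg = regularizer(out["U"], cfg.lambda1, cfg.lambda2)
                delta = (err.reshape(out["U"].shape) * surrogate_derivative(out["U"])
                         + dReg)
                grads = layer.gradients(delta.reshape(B, *layer.out_shape)
                                        if layer.kind == "conv" else delta,
                                        states[li], out["aux"])
                layer.params, _ = adamax_step(layer.params, grads, self.opt_states[li],
                                              eta, cfg.beta1, cfg.beta2, cfg.eps)
                if self.update_count % log_every == 0:
                    metrics.log(self.update_count, li, loss, reg, float(out["S"].mean()))
            self.update_count += 1
            metrics.n_updates += 1
        metrics.state_scalars = self.state_scalars(states)
        return metrics

    def evaluate_losses(self, frames: np.ndarray, targets: list) -> np.ndarray:
        """Per-layer mean readout loss over a sequence, no updates, no dropout."""
        net, cfg = self.net, self.cfg
        states = net.init_states(frames.shape[1])
        burn_steps = int(round(cfg.burn_in / net.spec.neuron.dt))
        totals = np.zeros(len(net.layers))
        count = 0
        for t in range(frames.shape[0]):
            states, outs = net.forward_step(states, frames[t], dropout_on=False)
            if t < burn_steps:
                continue
            count += 1
            for li, out in enumerate(outs):
                tgt = np.broadcast_to(targets[li][t], out["Y"].shape)
                loss, _ = loss_and_error(out["Y"], tgt, cfg.loss)
                totals[li] += loss
        return totals / max(count, 1)


def forward_step(net: Network, states: list, frame: np.ndarray, dropout_on: bool = False):
    """Functional wrapper around :meth:`Network.forward_step`."""
    return net.forward_step(states, frame, dropout_on)


def train_online(net: Network, frames: np.ndarray, targets: list,
                 cfg: TrainConfig, trainer: Trainer | None = None,
                 log_every: int = 50) -> Metrics:
    """Train on one time-aligned stream (T, B, ...); returns the metrics.

    Thin functional entry point over :class:`Trainer`; pass a ``trainer`` to
    continue across sequences with persistent optimizer state.
    """
    trainer = trainer if trainer is not None else Trainer(net, cfg)
    return trainer.train_sequence(frames, targets, log_every=log_every)


def evaluate_classification(net: Network, frames: np.ndarray, cfg: TrainConfig,
                            mode: str = "readout") -> np.ndarray:
    """Predicted class per layer from a (T, B, ...) stream.

    ``readout`` mode accumulates each layer's readout Y over the timesteps
    after burn-in and takes the argmax (ties -> lowest index).  ``spikes``
    mode counts the last layer's output spikes per unit instead (meaningful
    when that layer has one unit per class).  Dropout stays active when
    ``cfg.dropout_active_at_eval``.  Returns an (n_layers, B) integer array
    (``spikes`` mode fills only the last row, others are -1).
    """
    T, B = frames.shape[0], frames.shape[1]
    burn_steps = int(round(cfg.burn_in / net.spec.neuron.dt))
    if T <= burn_steps:
        raise ValueError(f"stream of {T} steps shorter than burn-in {burn_steps}")
    states = net.init_states(B)
    acc = [np.zeros((B, layer.readout.G.shape[0])) for layer in net.layers]
    spike_counts = np.zeros((B, net.layers[-1].n_out))
    for t in range(T):
        states, outs = net.forward_step(states, frames[t],
                                        dropout_on=cfg.dropout_active_at_eval)
        if t < burn_steps:
            continue
        for li, out in enumerate(outs):
            acc[li] += out["Y"]
        spike_counts += outs[-1]["S"].reshape(B, -1)
    if mode == "readout":
        return np.stack([a.argmax(axis=1) for a in acc])
    if mode == "spikes":
        preds = -np.ones((len(net.layers), B), dtype=int)
        preds[-1] = spike_counts.argmax(axis=1)
        return preds
    raise ValueError(f"unknown evaluation mode {mode!r}")
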