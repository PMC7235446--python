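# pydecolle

Online local learning for deep spiking neural networks, in pure numpy.

Spiking networks carry their state through time, so exact gradient training
(backpropagation through time) needs the whole activation history — memory
grows with sequence length, which rules it out for online or neuromorphic
settings.  This package implements the alternative known as DECOLLE (deep
continuous local learning): every layer of spiking neurons gets a **fixed
random readout** Y^l = G^l S^l and its own local loss L^l(Y^l, Ŷ^l), and each
synapse updates at every timestep with a closed-form **three-factor rule**

    ΔW_ij = −η · error_i · σ′(U_i) · P_j,    error_i = Σ_k H_ik ∂L/∂Y_k

— a modulatory factor (the readout error backprojected through fixed,
optionally sign-concordant feedback weights H), a post-synaptic factor (a
boxcar surrogate derivative gating on the membrane potential U), and a
pre-synaptic factor (the membrane trace P that the forward dynamics maintain
anyway).  No error crosses layer boundaries and no history is stored:
training memory is exactly the forward state plus optimizer accumulators,
independent of sequence length.

The neuron model is a discrete-time current-based leaky integrate-and-fire
unit in spike-response form (traces P, Q per input channel, relative
refractory trace R, threshold step with Θ(0)=1).  The package ships dense and
convolutional layers (with membrane max-pooling and dropout), the AdaMax
optimizer, per-step training with burn-in, and synthetic data generators:
Poisson spike trains, ramp/sinusoid pseudo-target traces, and a DVS-like
moving-bar event stream with polarity-correct leading/trailing edges, plus
event binning, spatial downsampling and random slicing.  It is a library and
CLI for studying the rule itself on synthetic tasks; it does not download or
train on external event datasets.

## Worked example

Train the three-layer regression demo — a stack of spiking layers driven by
one fixed 500 ms Poisson spike train, each layer regressing its random
readout onto its own pseudo-target (a ramp, a 20 Hz sinusoid, a 2 Hz
sinusoid):

```
$ pydecolle train-regression --units 32 --passes 30 --seed 1 --out-dir run1
{
  "initial_loss": [
    0.17110262828443346,
    0.20381581047018965,
    0.21248342515318533
  ],
  "final_loss": [
    0.05672039892219739,
    0.09383288369305105,
    0.07054762689118542
  ],
  "loss_ratio": [
    3.01659775910837,
    2.172114960645546,
    3.0119145677419534
  ],
  "n_updates": 15000,
  "weights_changed": [true, true, true]
}
```

`initial_loss`/`final_loss` are each layer's mean per-step readout MSE
½(Y−Ŷ)² on the training stimulus with frozen weights before and after 30
passes (15 000 online updates): every layer's readout tracks its target ~2–3×
better after training purely through local per-timestep updates.  `run1/`
holds the resolved config (re-running from it reproduces the numbers
bit-identically), a metrics CSV and a checkpoint archive; inspect the latter
with `pydecolle inspect run1/checkpoint.npz`.

The event-vision demo trains two convolutional spiking layers online on a
four-class moving-bar event stream (16×16 sensor, two polarity channels,
50 ms burn-in, dropout kept available at evaluation):

```
$ pydecolle train-classify --seed 1
{
  "n_updates": 3000,
  "test_error": [
    0.25,
    0.0
  ],
  "test_error_dropout": [
    0.25,
    0.0
  ],
  "test_accuracy": [
    0.75,
    1.0
  ]
}
```

giving per-layer held-out error — the deepest local readout separates the
four motion classes perfectly while the first layer's local classifier is
weaker, the signature layerwise division of labour of local-loss training.

As a library:

```python
import numpy as np
from pydecolle import (NetworkSpec, LayerSpec, TrainConfig, Trainer,
                       build_network, poisson_spike_train, regression_targets)

T = 500
stim = poisson_spike_train(np.full(100, 50.0), T, seed=0)[:, None, :]
targets = regression_targets(T)
spec = NetworkSpec(input_shape=(100,),
                   layers=[LayerSpec(kind="dense", n_units=64, n_targets=1)
                           for _ in range(3)])
net = build_network(spec, seed=0)
trainer = Trainer(net, TrainConfig(eta=1e-4))
metrics = trainer.train_sequence(stim, [targets[:, [i]] for i in range(3)])
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch — the regression task
(loss ratios per layer) and the moving-bar classification task (per-layer
test error) — and writes the results file.
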