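"""Discrete-time current-based leaky integrate-and-fire neurons with synaptic traces.

The neuron model is the discrete spike-response form of a current-based LIF
neuron.  Each *pre-synaptic channel* j carries two traces, a synaptic trace Q_j
(jump on input spike, exponential decay with tau_syn) and a membrane trace P_j
(low-pass of Q with tau_mem).  The membrane potential of neuron i is the
weighted sum of the P traces minus a refractory term:

    U_i[t] = sum_j W_ij P_j[t] - rho * R_i[t] + b_i
    S_i[t] = Theta(U_i[t]),            Theta(x) = 0 if x < 0 else 1
    P_j[t+dt] = alpha P_j[t] + (1 - alpha) Q_j[t]
    Q_j[t+dt] = beta  Q_j[t] + (1 - beta)  S_in_j[t]
    R_i[t+dt] = gamma R_i[t] + (1 - gamma) S_i[t]

with alpha = exp(-dt/tau_mem), beta = exp(-dt/tau_syn), gamma = exp(-dt/tau_ref).
Traces are per input channel, not per synapse, so state scales with the number
of pre-synaptic units.  For binary inputs and zero initial state all traces stay
in [0, 1]; integer event counts > 1 are accepted, in which case Q may exceed 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronConfig",
    "LayerState",
    "decay_constant",
    "init_state",
    "update_traces",
    "membrane_and_spike",
    "update_refractory",
    "step_layer",
    "heaviside",
]


def decay_constant(tau: float, dt: float) -> float:
    """Per-step decay factor exp(-dt/tau) for a first-order leak.

    Parameters
    ----------
    tau : float
        Time constant in ms, > 0.
    dt : float
        Simulation timestep in ms, > 0.

    Returns
    -------
    float
        exp(-dt/tau), strictly inside (0, 1).
    """
    if not (tau > 0):
        raise ValueError(f"time constant must be positive, got {tau}")
    if not (dt > 0):
        raise ValueError(f"timestep must be positive, got {dt}")
    return math.exp(-dt / tau)


@dataclass(frozen=True)
class NeuronConfig:
    """Time constants and derived decay factors of one neuron population.

    Defaults are conventional values for millisecond-resolution simulation:
    dt = 1 ms, tau_mem = 20 ms, tau_syn = 5 ms, tau_ref = 5 ms, rho = 1.
    The threshold is fixed at 0; excitability is set by the bias.
    """

    tau_mem: float = 20.0
    tau_syn: float = 5.0
    tau_ref: float = 5.0
    dt: float = 1.0
    rho: float = 1.0
    alpha: float = field(init=False)
    beta: float = field(init=False)
    gamma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"refractory weight rho must be >= 0, got {self.rho}")
        object.__setattr__(self, "alpha", decay_constant(self.tau_mem, self.dt))
        object.__setattr__(self, "beta", decay_constant(self.tau_syn, self.dt))
        object.__setattr__(self, "gamma", decay_constant(self.tau_ref, self.dt))


@dataclass
class LayerState:
    """Per-layer dynamic state, batch-first.

    P, Q are indexed by pre-synaptic channel; R, U by neuron; S is the binary
    spike output of the last step.  Arrays may carry extra spatial axes for
    convolutional layers (batch, channels, height, width).
    """

    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    U: np.ndarray
    S: np.ndarray

    def copy(self) -> "LayerState":
        return LayerState(*(a.copy() for a in (self.P, self.Q, self.R, self.U, self.S)))

    @property
    def n_scalars(self) -> int:
        """Number of persistent scalar state variables held by this layer."""
        return sum(a.size for a in (self.P, self.Q, self.R, self.U, self.S))


def init_state(
    batch_size: int,
    n_inputs: int,
    n_neurons: int,
    dtype=np.float64,
) -> LayerState:
    """All-zero state for a dense layer (resting network)."""
    for name, v in (("batch_size", batch_size), ("n_inputs", n_inputs), ("n_neurons", n_neurons)):
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    z_in = np.zeros((batch_size, n_inputs), dtype=dtype)
    z_out = np.zeros((batch_size, n_neurons), dtype=dtype)
    return LayerState(P=z_in, Q=z_in.copy(), R=z_out, U=z_out.copy(), S=z_out.copy())


def update_traces(P, Q, S_in, alpha: float, beta: float):
    """Advance the membrane and synaptic traces by one step.

    P' is computed from the *pre-update* Q (P[t+dt] depends on Q[t]); Q' then
    absorbs the current input spikes.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    S_in = np.asarray(S_in, dtype=float)
    if P.shape != Q.shape or Q.shape != S_in.shape:
        raise ValueError(f"shape mismatch: P{P.shape}, Q{Q.shape}, S_in{S_in.shape}")
    P_new = alpha * P + (1.0 - alpha) * Q
    Q_new = beta * Q + (1.0 - beta) * S_in
    return P_new, Q_new


def heaviside(U: np.ndarray) -> np.ndarray:
    """Unit step with Theta(0) = 1."""
    return (np.asarray(U) >= 0.0).astype(float)


def membrane_and_spike(P, R, W, b, rho: float):
    """Membrane potential U = W.P - rho*R + b and threshold spike S = Theta(U)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if W.ndim != 2 or W.shape[1] != P.shape[-1]:
        raise ValueError(f"weight shape {W.shape} incompatible with input of {P.shape[-1]} channels")
    if R.shape[-1] != W.shape[0]:
        raise ValueError(f"refractory state of {R.shape[-1]} units, layer has {W.shape[0]}")
    U = P @ W.T - rho * R + b
    return U, heaviside(U)


def update_refractory(R, S, gamma: float):
    """Advance the refractory trace: R' = gamma*R + (1-gamma)*S."""
    R = np.asarray(R, dtype=float)
    S = np.asarray(S, dtype=float)
    if R.shape != S.shape:
        raise ValueError(f"shape mismatch: R{R.shape}, S{S.shape}")
    return gamma * R + (1.0 - gamma) * S


def step_layer(state: LayerState, S_in, W, b, config: NeuronConfig):
    """One full timestep of a dense layer; purely functional.

    Order within the step: traces advance first (P from the old Q, Q from the
    input spikes), then U and S are computed from the new P and the old R, then
    R advances using the new S.  Returns the complete next state and the spikes.
    """
    P, Q = update_traces(state.P, state.Q, S_in, config.alpha, config.beta)
    U, S = membrane_and_spike(P, state.R, W, b, config.rho)
    R = update_refractory(state.R, S, config.gamma)
    return LayerState(P=P, Q=Q, R=R, U=U, S=S), S
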