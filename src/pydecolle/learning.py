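"""The DECOLLE learning rule: local random readouts, surrogate gradients, AdaMax.

Each spiking layer projects its spikes through a fixed random readout
Y = G.S and is trained against its own pseudo-target Y_hat with a local loss.
The weight update is a closed-form three-factor rule,

    dW_ij = -eta * error_i * boxcar(U_i) * P_j,
    error_i = sum_k H_ik * dL/dY_k,

where the post-synaptic factor boxcar(U) is the derivative of a piecewise
linear (hard-sigmoid) surrogate of the spike step, the pre-synaptic factor is
the membrane trace P, and the modulatory factor is the readout error projected
back through H.  H is either G transposed exactly, or a sign-concordant random
matrix (G transposed times non-negative Gaussian noise, feedback alignment).
No state beyond the forward traces is required, so the training memory
footprint is independent of the sequence length.

Two membrane regularizers keep the firing rate reasonable: one pushes U below
threshold on average, one enforces a minimum firing rate per layer.  They act
on U directly (U is linear in W), so their gradient bypasses the boxcar gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReadoutConfig",
    "LossSpec",
    "AdaMaxState",
    "surrogate_derivative",
    "build_readout",
    "build_feedback",
    "local_readout",
    "loss_and_error",
    "backproject_error",
    "decolle_gradient",
    "conv_decolle_gradient",
    "im2col",
    "regularizer",
    "adamax_init",
    "adamax_step",
]

BOXCAR_HALF_WIDTH = 0.5


def surrogate_derivative(U) -> np.ndarray:
    """Boxcar surrogate derivative: 1 where -0.5 <= U <= 0.5 (inclusive), else 0."""
    U = np.asarray(U, dtype=float)
    return ((U >= -BOXCAR_HALF_WIDTH) & (U <= BOXCAR_HALF_WIDTH)).astype(float)


def build_readout(n_units: int, n_targets: int, seed) -> np.ndarray:
    """Fixed random readout matrix G of shape (n_targets, n_units).

    Entries are uniform on [-1/sqrt(n_units), +1/sqrt(n_units)].  G is drawn
    once and never trained.
    """
    if n_units < 1 or n_targets < 1:
        raise ValueError(f"counts must be >= 1, got {n_units}, {n_targets}")
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(n_units)
    return rng.uniform(-bound, bound, size=(n_targets, n_units))


def build_feedback(
    G: np.ndarray,
    seed,
    concordant: bool = True,
    omega_mean: float = 1.0,
    omega_var: float = 0.5,
) -> np.ndarray:
    """Fixed feedback matrix H of shape (n_units, n_targets).

    With ``concordant=False`` the feedback is the exact transpose of the
    readout, H = G.T.  With ``concordant=True`` each entry is G.T times an
    independent multiplicative noise max(omega, 0) with omega ~ N(omega_mean,
    omega_var): the feedback keeps the sign of the forward weight (or is zero)
    but not its magnitude — sign-concordant feedback alignment.
    """
    G = np.asarray(G, dtype=float)
    if not concordant:
        return G.T.copy()
    rng = np.random.default_rng(seed)
    omega = rng.normal(omega_mean, np.sqrt(omega_var), size=G.T.shape)
    return G.T * np.maximum(omega, 0.0)


@dataclass
class ReadoutConfig:
    """A layer's fixed readout G and feedback H plus their provenance."""

    G: np.ndarray
    H: np.ndarray
    concordant: bool
    seed: int

    @classmethod
    def create(cls, n_units: int, n_targets: int, seed: int, concordant: bool = True,
               omega_mean: float = 1.0, omega_var: float = 0.5) -> "ReadoutConfig":
        G = build_readout(n_units, n_targets, seed)
        H = build_feedback(G, seed + 1, concordant, omega_mean, omega_var)
        return cls(G=G, H=H, concordant=concordant, seed=seed)


def local_readout(S, G) -> np.ndarray:
    """Instantaneous readout Y = G.S; no temporal state."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    G = np.asarray(G, dtype=float)
    if S.shape[-1] != G.shape[1]:
        raise ValueError(f"spikes of {S.shape[-1]} units, readout expects {G.shape[1]}")
    return S @ G.T


def loss_and_error(Y, Y_hat, kind: str = "mse", delta: float = 1.0):
    """Local loss value and its gradient dL/dY.

    ``mse``: L = 1/2 sum (Y - Y_hat)^2, gradient Y - Y_hat.
    ``smooth_l1``: quadratic inside |Y - Y_hat| <= delta, linear outside;
    the gradient is the residual clipped to [-delta, delta].
    Batched inputs (first axis) average the loss over the batch; the gradient
    is returned per element (batch averaging happens in the weight update).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: Y{Y.shape}, Y_hat{Y_hat.shape}")
    r = Y - Y_hat
    if kind == "mse":
        loss = 0.5 * np.sum(r * r, axis=-1)
        dLdY = r
    elif kind == "smooth_l1":
        a = np.abs(r)
        quad = a <= delta
        loss = np.sum(np.where(quad, 0.5 * r * r / delta, a - 0.5 * delta), axis=-1)
        dLdY = np.where(quad, r / delta, np.sign(r))
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return float(np.mean(loss)), dLdY


@dataclass
class LossSpec:
    """Loss kind, per-layer pseudo-targets and regularizer weights."""

    kind: str = "mse"
    lambda1: float = 0.05
    lambda2: float = 0.05
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("mse", "smooth_l1"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularizer weights must be >= 0")


def backproject_error(dLdY, H) -> np.ndarray:
    """Per-neuron error: error_i = sum_k H_ik dL/dY_k."""
    dLdY = np.atleast_2d(np.asarray(dLdY, dtype=float))
    H = np.asarray(H, dtype=float)
    if dLdY.shape[-1] != H.shape[1]:
        raise ValueError(f"error of {dLdY.shape[-1]} targets, feedback expects {H.shape[1]}")
    return dLdY @ H.T


def decolle_gradient(error, U, P):
    """Three-factor gradient for a dense layer.

    gW_ij = error_i * boxcar(U_i) * P_j, gb_i = error_i * boxcar(U_i);
    batched inputs are averaged over the batch.
    """
    error = np.atleast_2d(np.asarray(error, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if error.shape != U.shape:
        raise ValueError(f"shape mismatch: error{error.shape}, U{U.shape}")
    if error.shape[0] != P.shape[0]:
        raise ValueError("batch size mismatch between error and P")
    delta = error * surrogate_derivative(U)
    B = error.shape[0]
    gW = delta.T @ P / B
    gb = delta.mean(axis=0)
    return gW, gb


def im2col(x: np.ndarray, kh: int, kw: int, padding: int = 0) -> np.ndarray:
    """Unroll sliding (kh, kw) patches of a (B, C, H, W) map.

    Returns (B, Ho*Wo, C*kh*kw) with Ho = H + 2*padding - kh + 1 (stride 1).
    """
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (B, C, Ho, Wo, kh, kw) -> (B, Ho*Wo, C*kh*kw)
    B, C, Ho, Wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho * Wo, C * kh * kw)


def conv_decolle_gradient(error_map, U_map, P_map, kernel_shape, padding: int = 0):
    """Three-factor gradient for a convolutional layer (stride 1).

    The kernel gradient sums error * boxcar(U) at each output position times
    the corresponding input-trace patch of P; the bias gradient sums
    error * boxcar(U) over positions.  Identical to :func:`decolle_gradient`
    applied to the unrolled patch matrix.  Batched inputs average over the
    batch axis.
    """
    error_map = np.asarray(error_map, dtype=float)
    U_map = np.asarray(U_map, dtype=float)
    P_map = np.asarray(P_map, dtype=float)
    if error_map.ndim == 3:  # unbatched (C, H, W)
        error_map, U_map, P_map = error_map[None], U_map[None], P_map[None]
    C_out, C_in, kh, kw = kernel_shape
    if error_map.shape != U_map.shape or error_map.shape[1] != C_out:
        raise ValueError("error/U map geometry inconsistent with kernel")
    Ho = P_map.shape[2] + 2 * padding - kh + 1
    Wo = P_map.shape[3] + 2 * padding - kw + 1
    if error_map.shape[2:] != (Ho, Wo):
        raise ValueError(
            f"output map {error_map.shape[2:]} does not match kernel geometry {(Ho, Wo)}")
    delta = error_map * surrogate_derivative(U_map)  # (B, C_out, Ho, Wo)
    patches = im2col(P_map, kh, kw, padding)  # (B, Ho*Wo, C_in*kh*kw)
    B = delta.shape[0]
    d = delta.reshape(B, C_out, Ho * Wo)
    gW = np.einsum("bcp,bpk->ck", d, patches) / B
    gb = d.sum(axis=2).mean(axis=0)
    return gW.reshape(C_out, C_in, kh, kw), gb


def regularizer(U, lambda1: float, lambda2: float):
    """Membrane regularizer value and gradient dReg/dU.

    reg = lambda1 * <relu(U_i + 0.01)>_i + lambda2 * relu(0.1 - <U_i>_i),
    averaging over neurons i.  The first term keeps U below threshold on
    average; the second enforces a minimum firing rate (layers must not go
    silent).  The gradient acts on U directly (no boxcar gate): U is linear in
    the weights, so this contributes error-free through dU/dW = P.  Batched U
    averages the value over the batch; the gradient is per element.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularizer weights must be >= 0")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    B = U.shape[0]
    flat = U.reshape(B, -1)
    n = flat.shape[1]
    mean_U = flat.mean(axis=1)
    term1 = lambda1 * np.maximum(flat + 0.01, 0.0).mean(axis=1)
    term2 = lambda2 * np.maximum(0.1 - mean_U, 0.0)
    reg = float(np.mean(term1 + term2))
    grad = (lambda1 / n) * (flat > -0.01).astype(float) \
        - (lambda2 / n) * (mean_U < 0.1).astype(float)[:, None]
    return reg, grad.reshape(U.shape)


@dataclass
class AdaMaxState:
    """First-moment and infinity-norm accumulators for one list of parameters."""

    m: list = field(default_factory=list)
    u: list = field(default_factory=list)
    t: int = 0

    @property
    def n_scalars(self) -> int:
        return sum(a.size for a in self.m) + sum(a.size for a in self.u)


def adamax_init(params) -> AdaMaxState:
    """Zero-initialized optimizer state matching a list of parameter arrays."""
    return AdaMaxState(
        m=[np.zeros_like(np.asarray(p, dtype=float)) for p in params],
        u=[np.zeros_like(np.asarray(p, dtype=float)) for p in params],
        t=0,
    )


def adamax_step(
    params,
    grads,
    state: AdaMaxState,
    eta: float,
    beta1: float = 0.0,
    beta2: float = 0.95,
    eps: float = 1e-8,
):
    """One AdaMax update; returns (new_params, state).

    m <- beta1*m + (1-beta1)*g;  u <- max(beta2*u, |g|);
    p <- p - eta/(1-beta1^t) * m/(u+eps).
    With beta1 = 0 (the default here) the first step moves each coordinate by
    eta*sign(g).  The state is mutated in place and also returned.
    """
    if state is None or not state.m:
        raise ValueError("optimizer state not initialized; call adamax_init first")
    if len(params) != len(grads) or len(params) != len(state.m):
        raise ValueError("params/grads/state length mismatch")
    state.t += 1
    bias = 1.0 - beta1 ** state.t if beta1 > 0 else 1.0
    new_params = []
    for i, (p, g) in enumerate(zip(params, grads)):
        g = np.asarray(g, dtype=float)
        state.m[i] = beta1 * state.m[i] + (1.0 - beta1) * g
        state.u[i] = np.maximum(beta2 * state.u[i], np.abs(g))
        new_params.append(p - (eta / bias) * state.m[i] / (state.u[i] + eps))
    return new_params, state
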