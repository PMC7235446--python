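# Methods

## The model

The simulator implements discrete-time, current-based leaky integrate-and-fire
neurons in spike-response form.  Each pre-synaptic channel *j* carries a
synaptic trace Q_j (unit-height jump per input spike, exponential decay with
τ_syn) and a membrane trace P_j (low-pass of Q with τ_mem).  Neuron *i* of a
layer computes

    U_i[t] = Σ_j W_ij P_j[t] − ρ R_i[t] + b_i,     S_i[t] = Θ(U_i[t]),

with Θ(0) = 1, and a relative-refractory trace R_i that is charged by the
neuron's own spikes (decay τ_ref) and subtracted with weight ρ.  Traces are
per input channel, not per synapse, so the state grows linearly in the number
of pre-synaptic units.  The discrete updates use factors α = exp(−Δt/τ_mem),
β = exp(−Δt/τ_syn), γ = exp(−Δt/τ_ref) with input gains (1−α), (1−β), (1−γ),
which bounds all traces by 1 for binary inputs.  Within a timestep, traces
advance first (P from the previous Q, Q from the current input), then U and S
are computed from the new P and the old R, then R advances with the new S.
Binned event counts larger than 1 are accepted as input, in which case Q may
exceed 1.

Defaults (the original DECOLLE experiments do not fix these; ours are standard
millisecond-scale conventions, all exposed in the config): Δt = 1 ms,
τ_mem = 20 ms, τ_syn = 5 ms, τ_ref = 5 ms, ρ = 1.  The threshold is fixed at
0; biases are initialised at −0.01 so resting neurons sit just below
threshold, inside the surrogate window.

## The learning rule

Every layer owns a fixed random readout Y = G·S (G uniform on
±1/√n_units, never trained) and a local loss L(Y, Ŷ) against its own
pseudo-target.  The weight update is the closed-form three-factor rule

    ΔW_ij = −η · error_i · σ′(U_i) · P_j,      error_i = Σ_k H_ik ∂L/∂Y_k,

with σ′ the boxcar surrogate derivative (1 on [−0.5, 0.5], 0 elsewhere) and
H either the exact transpose Gᵀ or, by default, sign-concordant feedback
Gᵀ·max(ω, 0) with fixed multiplicative noise ω ~ N(1, ½).  Biases train with
the same rule (∂U/∂b = 1).  The refractory dependence ∂R/∂W is deliberately
dropped; two membrane regularizers compensate:

    reg = λ1 ⟨[U_i + 0.01]⁺⟩_i + λ2 [0.1 − ⟨U_i⟩_i]⁺,

whose gradient acts on U directly (U is linear in W, so no boxcar gate).
Convolutional layers apply the identical rule to the im2col-unrolled patch
matrix; max-pooling on the membrane map routes each pooled error to the
argmax pre-pool position.  Dropout masks the spike output feeding both the
next layer and the local readout, and the mask (with its 1/(1−p) scale)
multiplies the backprojected error.  The optimizer is AdaMax; updates are
applied at every simulation step after a burn-in, with gradients averaged
(not summed) over the batch so η keeps its meaning across batch sizes.

Because the error is local and instantaneous, the persistent training state
is exactly the forward state plus parameters, readouts and optimizer
accumulators — independent of the sequence length.  This is asserted by the
memory-constancy test.

The surrogate-gradient chain rule is certified without any autodiff
framework: on random single-timestep instances the closed-form update equals
central finite differences of the relaxed loss L(G·σ_lin(U(W))) + reg(U(W)),
with σ_lin(x) = clip(x + 0.5, 0, 1), at points away from the kinks.  Note
the forward network emits binary spikes while the surrogate differentiates
the relaxed map — the two differ by design.

## Synthetic tasks

**Regression.**  Three fully connected layers (64 units each in the test
configuration, 512 in the full-scale template) driven by one fixed 500 ms
Poisson spike train (100 units at 50 Hz; the source ensemble is not fixed by the original experiments
and these are ordinary cortical-input-like values).  Layer *l* regresses its
one-dimensional readout onto Ŷ¹ a 0→1 ramp, Ŷ² a 20 Hz sinusoid, Ŷ³ a 2 Hz
sinusoid (the original demonstration leaves the frequencies open; 20/2 Hz give one fast and one slow
component resolvable in 500 ms), all scaled to [0, 1], MSE loss, no burn-in
(targets start at the resting readout value).  η = 1e−4 (the original experiments' 1e−9
is tuned to GPU-scale batches and loss sums; with per-step sign-normalised
AdaMax steps it would not move the weights measurably in a desk-scale run),
λ1 = λ2 = 0.05, 200 passes.

Known limitation, quantified: with 64 binary units per layer and
τ_mem = 20 ms, the P-traces attenuate 20 Hz content roughly 3×, and an
*oracle* least-squares readout (free weights and bias, strictly more
expressive than the fixed bias-free G) fitted to the trained spike trains
still leaves a loss of ≈0.060 on the 20 Hz target and ≈0.024 on the 2 Hz
target, against initial losses of ≈0.18–0.20.  A 10× per-layer reduction is
therefore not reachable at this scale regardless of training rule; the
online rule itself achieves ≈6× / 1.5× / 4.5× (ramp / 20 Hz / 2 Hz).  The
corresponding acceptance test states the 10× bar and fails honestly.  The
η = 0 control (bit-identical weights, exactly repeating loss trace) passes.

**Classification.**  An explicit synthetic stand-in for event-camera gesture
recognition, never claimed to reproduce published benchmark numbers.  A
bright bar sweeps a 16×16 two-polarity sensor; its leading edge emits ON
events and its trailing edge OFF events each step, with ±0.25 ms timestamp
jitter and 1 Hz/pixel background noise (typical DVS figures).  Each of the
four classes (L→R, R→L, T→B, B→T) wraps within the half of the sensor
adjacent to its entry side.  The half-sensor confinement is load-bearing:
a full-sensor periodic sweep has class-independent time-averaged pixel
statistics (mirror directions are exactly identical), and since the
per-sequence error direction is constant, the first-order content of the
three-factor update is error ⊗ (gate-weighted time-averaged traces) — a
full-sweep task is invisible to it and training stays at chance.  Confining
each class to its own half makes the per-class pixel means linearly
separable, the stated precondition of the task design.

Network: conv(8 ch, 5×5, pad 2) → 2×2 max-pool → conv(16 ch, 3×3, pad 1) →
2×2 max-pool, dropout 0.5 on both spike outputs, 4-target readouts per
layer, per-step constant one-hot pseudo-targets, smooth-L1 loss (transition
δ = 1), 50 ms burn-in (hence 250 updates per 300 ms sequence), η = 1e−3
divided by 5 every 1500 steps (the original /5-every-500 cadence rescaled
to the shorter run), 6 epochs over 32 training sequences in batches of 16,
evaluation by accumulated-readout argmax (ties to the lowest index) on 100
held-out sequences.  The 32×32 architecture template with 7×7 kernels,
padding 2 and pools 2/1/2 reproducing the 15×15 → 13×13 → 5×5 dimension
chain is available and unit-tested, but the 16×16 task above is what the
acceptance test exercises.  The deepest readout reaches 100% held-out
accuracy in 10/10 seeds.  An untrained network is at chance only in
expectation over readout draws: a fixed random readout maps the (already
separated) class clusters onto argmax cells by luck, so a single seed's
untrained accuracy lands on {0, ¼, ½, …}; across the 10 seeds the mean is
0.276, and the chance check in the test is applied to that mean.

What a green classification test does and does not establish: the generator
emulates edge-polarity structure, timestamp jitter and background noise of a
real event camera, but not sensor refractoriness, per-pixel threshold
mismatch, scene texture, or class overlap — real gesture data is far harder,
and the 100% accuracies here say nothing about benchmark error rates.

## Numerical choices

- Θ(0) = 1 and boxcar boundaries inclusive, exactly as defined.
- AdaMax: β1 = 0, β2 = 0.95 (the original experiments state "β2 = 95", read as 0.95 — a valid
  decay factor must be < 1), ε = 1e−8 in the denominator; with β1 = 0 the
  bias-correction term is inert.  ω's "N(1, 12)" is read as variance ½; both
  moments are config fields.
- Smooth-L1 transition point δ = 1 (not fixed by the original experiments).
- Max-pool truncates odd trailing dimensions; pooled error routes to the
  within-window argmax (first occurrence on exact ties, numpy convention).
- Argmax classification ties break to the lowest class index.
- State resets between sequences (carrying state across minibatch boundaries
  is left open in the original experiments; burn-in re-equilibrates after each reset).
- Poisson trains are per-bin Bernoulli(rate·Δt), standard at 1 ms bins.
- One master seed; per-layer weight/readout/dropout streams derived via
  seed sequences, so perturbing one layer never shifts another's draws.

## Known limitations

- The 20 Hz regression target is beyond the spike-train information content
  at 64 units with the default time constants (quantified above).
- Stride is fixed at 1 for convolutions; pooling windows are 2×2.
- The "count output spikes" evaluation mode is only meaningful when the last
  layer has one unit per class; the default mode accumulates readouts.
- No recurrent (lateral) connectivity, no axonal delays, no stochastic decay,
  no training of the readouts.
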