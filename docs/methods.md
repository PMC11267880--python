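# Methods

## Model

The network is a single-hidden-layer recurrent neural network with a linear
readout:

    x_t = tanh(A u_t + R x_{t-1}),    y_t = B x_t,

with input weights `A` (hidden × input), recurrent weights `R`
(hidden × hidden) and readout `B` (output × hidden). The per-timestep loss
is the squared error `ℓ_t = ||y_t − y*_t||²` and the sequence loss is its
mean, `L = (1/T) Σ_t ℓ_t`. The initial hidden state is zero and is reset at
the start of every sequence. Weights are initialized uniformly in
`[−1/√fan_in, +1/√fan_in]`, which keeps the tanh units in their sensitive
range at initialization.

With the decorrelation mechanism enabled, a learned linear transform `D`
(initialized to the identity) is inserted after the nonlinearity:

    x*_t = D x_t,    x_t = tanh(A u_t + R x*_{t-1}),    y_t = B x*_t,

so both the recurrence and the readout consume the decorrelated state. Only
the hidden units are decorrelated — the task inputs are low-dimensional and
are passed through untouched.

## Learning rules

All perturbation rules run two forward passes per sequence: a clean pass
and a noisy pass in which fresh zero-mean Gaussian noise (std `σ`) is
injected at every timestep. The noisy pass propagates its **own** recurrent
state `x̃_{t−1}`, exactly as the update equations are written; running the
two passes sequentially or as two parallel model copies is an
implementation freedom with no semantic difference.

Per-timestep loss differences `δℓ_t = ℓ̃_t − ℓ_t` act as local
reinforcement signals. Writing `presyn_t` for the activity feeding a weight
matrix (`u_t` for `A`, `x_t` — or `x*_t` — for `B`, `x_{t−1}` — or
`x*_{t−1}` — for `R`):

* **NP (local)**: `ΔW = σ⁻² Σ_t δℓ_t · noise_t · presyn_tᵀ`, where
  `noise_t` is the pre-activation noise (`ξ_t` hidden, `ν_t` output).
* **NP (global)**: the conventional variant, with the single per-sequence
  signal `δL = L̃ − L` replacing `δℓ_t` outside the sum.
* **WP (local/global)**: the same with noise injected into the weight
  matrices themselves; the noise already has weight shape, so no
  presynaptic factor appears. The global variant sums the per-timestep
  weight noise over the sequence before scaling by `δL`.
* **ANP**: replaces the raw noise with the measured pre-activation
  differences `δα_t = α̃_t − α_t`, `δβ_t = β̃_t − β_t`, normalized by their
  squared magnitude and scaled by the total neuron count `N`:
  `ΔW = N Σ_t δℓ_t · δ_t/(||δα_t||² + ||δβ_t||²) · presyn_tᵀ`. This is a
  per-timestep directional-derivative estimate: because
  `E[||δα||² + ||δβ||²] ≈ Nσ²`, the `N/||δ||²` factor plays the role of
  `σ⁻²` while adapting to the *realized* perturbation magnitude, which both
  aligns the expected update more closely with the gradient and lowers its
  per-sample variance relative to NP.
* **BPTT baseline**: the exact gradient `∇L`, computed by hand-written
  reverse-mode accumulation through the unrolled recurrence and applied
  through Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e−8). It is verified against
  central finite differences (h = 1e−6, double precision) to < 1e−5 max
  relative error on random small instances, including the decorrelated
  architecture. When `D` is present the gradient flows *through* `D` but
  `D` itself is never gradient-trained.

Updates are applied as `W ← W − ηΔW` by plain SGD (perturbation rules) or
Adam (BPTT only). Following the update equations, the per-sequence sums are
**not** divided by `T`; the `1/T` lives only in `L`. No gradient or update
clipping is applied — instability is detected and reported, not masked.

### Normalization and pairing conventions

Two places where the commonly printed forms of these rules are internally
inconsistent are resolved here, each with the literal form kept behind a
flag for auditability:

1. **Presynaptic pairing.** The printed node-level updates pair `ΔA` with
   `x_tᵀ` and `ΔB` with `u_tᵀ`, which contradicts the wiring (`A` reads
   `u_t`, `B` reads the hidden state) and is shape-inconsistent except for
   square networks. Default `presynaptic_convention="corrected"` pairs each
   noise term with the activity its synapse actually receives;
   `"as_printed"` keeps the literal pairing.
2. **ANP normalization.** The printed ANP rule normalizes each layer's
   activity difference by its own norm while scaling by the *total* neuron
   count `N`. Measured on a fixed 3-unit instance (10⁴ draws, σ = 1e−3),
   that combination inflates the mean update ≈2× relative to the gradient
   scale and gives per-sample variance ≈5× NP's, destroying ANP's variance
   advantage. Normalizing by the whole-network difference norm
   `||δα_t||² + ||δβ_t||²` — the construction ANP's feedforward derivation
   uses — restores the directional-derivative scaling (variance ≈0.55× NP's
   at matched σ). Default `anp_normalization="joint"`; `"per_layer"` keeps
   the literal form.

Two further ambiguities are resolved as follows: the ANP reinforcement
signal defaults to the loss *difference* `δℓ_t` (the printed `ℓ_t` is
nonnegative and cannot encode improvement vs. worsening; a flag restores
it), and the noisy pass propagates its own recurrent state as the equations
are written.

### Decorrelation rule

`D` learns by the anti-Hebbian rule `ΔD = Σ_t (x*_t x*_tᵀ − diag((x*_t)²)) D`,
applied as `D ← D − ϵΔD` in parallel with the forward weights, from the
clean pass. Its expected update vanishes exactly when the covariance of
`x*` is diagonal. The decorrelation loss is the mean squared
strictly-lower-triangular entry of the empirical covariance of `x*`, pooled
over timesteps.

## Training protocol

An epoch is one full pass over the training sequences, visited in a fixed
seeded order. The default cadence accumulates each rule's update over one
sequence and applies it once; an online mode that applies per-timestep
updates immediately is provided for the local rules (`np_local`, `anp`,
`wp_local` — the global variants and BPTT are inherently sequence-level).
Evaluation always uses clean, noise-free passes. Each experiment runs five
seeds; aggregates report the mean with min/max bands, and the summary
metric ("final performance") is the mean test loss over the last 50 epochs.

A run is flagged unstable and aborted when any loss is non-finite or
exceeds 1e6, or any weight magnitude exceeds 1e6 (the divergence mode of
perturbation rules at scale is extreme weight growth; the numeric threshold
is this package's own declaration). Scalability sweeps report, per
(hidden-size, rule) cell, the stable-run count and the mean final
performance over the stable runs only; a cell with no stable runs reports
an empty (NaN) value.

All randomness flows from one root seed per run, expanded through
`numpy.random.SeedSequence` spawning so that initialization, noise draws
and sequence order are independent streams and adding one consumer does not
perturb another's draws.

## Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| σ | 1e−3 | perturbation std (node or weight), per timestep |
| η | 1e−4 (perturbation), 1e−3 (BPTT+Adam) | learning rate |
| ϵ | 1e−5 | decorrelation learning rate |
| hidden units | 64 | hidden-layer width |
| seeds | 5 | runs per experiment |
| final window | 50 | epochs averaged for final performance |

Because the per-sequence updates sum over `T` timesteps un-normalized,
usable `η` scales roughly like 1/T; at T = 500 the stable window for the
perturbation rules sits near η = 1e−4, and a few-fold larger η destabilizes
them — consistent with instability being a real failure mode of these
rules rather than an artifact.

## Synthetic tasks

* **Mackey-Glass**: `dx/dt = βx(t−τ)/(1+x(t−τ)ⁿ) − γx(t)` with the
  canonical benchmark constants β = 0.2, γ = 0.1, n = 10, unit-step Euler
  integration, constant history x(t ≤ 0) = 1.2 (plus a small seed-dependent
  jitter to separate realizations) and 100 burn-in steps. Defaults: τ = 17
  (chaotic regime; τ = 2 relaxes to a fixed point), prediction horizon 15,
  5000 steps. The task is one-step windows: input x(t), target x(t+horizon).
* **Copying memory**: `n_symbols + 2` input channels (one-hot symbols, a
  delay marker active through the delay period, a recall cue one step
  before the recall window); timeline `seq_len + delay + 1 + seq_len`;
  targets are zero (blank) outside the recall window and the original
  one-hot sequence inside it. Squared error is used throughout, consistent
  with the single loss definition above. Defaults: sequence length 100,
  delay 10, 8 symbols.
* **Synthetic weather**: a surrogate for hourly climate records. Every
  channel is a shared period-24 sinusoid (per-channel random coupling and
  phase) plus independent AR(1) noise (coefficient 0.8); channel 0 plays
  the temperature role and is predicted `horizon ∈ {1, 24, 48}` steps
  ahead. Its lag-24 autocorrelation exceeds 0.9 at the defaults. Splits are
  chronological (train on early windows, test on the last), emulating
  training on early months and testing on the final ones. What it does
  *not* emulate: weather fronts, seasonal drift, cross-feature causal
  structure, missing data. Results on it show the learning rules work on a
  smooth autocorrelated multivariate prediction problem, not that they
  match any result on real climate data.

Continuous-task inputs and targets are z-scored using train-split
statistics only. Real hourly weather CSVs (one row per hour, named feature
columns) can be adapted by constructing a `SequenceDataset` directly; no
bundled experiment depends on external data.

## Scaled-down experiment sizes

The package's own benchmark configurations (used by the test suite and
`scripts/acceptance.py`) are deliberately small: Mackey-Glass with five
chronological 500-step windows (four train, one test), 64 hidden units,
200 epochs, five seeds; the weather comparison with five 200-step windows,
32 hidden units, 100 epochs; Monte-Carlo rule-alignment estimates with 10⁴
draws on a 3-unit, T = 3 instance. At these sizes the qualitative ordering
(ANP ≈ BPTT ≫ NP, WP; decorrelation lowers the decorrelation loss without
zeroing it) is already expressed while a full run completes in minutes on
one CPU. Larger configurations are a matter of changing the config file,
not the code.

## Known limitations

* The per-timestep reinforcement signal assumes the loss is available at
  every step; tasks with delayed or sparse rewards favor the global
  variants.
* Monte-Carlo alignment statements are statistical: single updates are
  extremely noisy, and only their mean aligns with the gradient.
* The online cadence changes parameters mid-sequence, so its trajectory is
  not exactly the one any of the batch equations describe; it is provided
  as the natural streaming variant of the local rules.
* The instability threshold is a declared engineering constant, not an
  estimate of any intrinsic quantity.
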