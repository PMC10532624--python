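# Methods

## Diffusion process

The forward process is the variance-preserving Gaussian diffusion
q(z_t | x) = N(α_t x, σ_t² I) on continuous time t ∈ [0, 1], parameterized
through a scalar log-SNR schedule γ(t) with σ_t² = logistic(γ(t)) and
α_t² = logistic(−γ(t)). This mapping makes α_t² + σ_t² = 1 an algebraic
identity (checked to 10⁻¹² over random γ) and gives SNR(t) = exp(−γ(t)),
strictly decreasing whenever γ is increasing. Transitions q(z_t | z_s) and
posteriors q(z_s | z_t, x) follow by Gaussian conjugacy; the implementation
exposes their coefficients in closed form and the tests compare them against
a grid-quadrature Bayes inversion (max density error < 10⁻³) and
Monte-Carlo moment composition (4-standard-error tolerance at 10⁵ draws).

The default schedule is linear from γ_min = 0.1 to γ_max = 1.0, evaluated
exactly; a 50-step × 1000-substep tabulation grid is provided for schedule
inspection. This narrow range implies SNR(1) ≈ 0.37, i.e. z_1 retains
substantial signal and the prior KL (latent loss) is never close to zero; the
range is a deliberate, configurable default rather than a structural
constraint, and several analytic tests use wider ranges (e.g. γ ∈ [−8, 8])
where near-complete noising is mathematically required. The alternative
learned schedule is a one-hidden-layer network whose weights pass through a
softplus reparameterization on top of a unit linear term,
g(t) = t + Σ_k softplus(w2_k)·sigmoid(softplus(w1_k) t + b_k), affinely
rescaled to hit the endpoints; monotonicity therefore holds for *every*
parameter draw, a structural property the tests verify on 100 random draws ×
1000 sorted times.

## Networks

All networks are dense ResNets on flattened inputs, matching an encoder that
begins with a dense layer; at 256² a dense stem is large, so the test and
`fast`-preset configuration uses 16×16 images while keeping every other
architectural constant (latent 64, 6+6 encoder/decoder blocks, ScoreNet
embedding 128 with 10 FiLM-conditioned residual layers) at its published
value. Residual blocks are two dense layers with swish and an additive
skip; the final layer of each residual branch is zero-initialized so a fresh
network starts near its skip path. The ScoreNet is an ε-prediction network:
its conditioning vector is built from a sinusoidal embedding of γ_t
(geometric frequencies 10⁰…10⁴), optionally concatenated with a
class-conditioning vector (length 0 by default), passed through two
swish-activated dense layers and a linear head; FiLM applies a per-block
(1 + scale, shift) modulation. The decoder ends in per-pixel Bernoulli
logits — a mean-field observational model whose likelihood factorizes over
pixels exactly, which the tests confirm against a per-pixel loop.

Because no automatic-differentiation framework is part of the package's
dependency set, `medvdm.autodiff` implements a small tape-based reverse-mode
engine over numpy (≈20 primitives with broadcasting-aware gradients) plus
the pytree utilities used for parameter storage. Its gradients are tested
against central finite differences.

## Objective

Reported losses are nats per image (summed over pixels/dimensions, averaged
over the batch). The diffusion term uses the continuous-time form
½ E[γ′(t)‖ε − ε̂‖²] during training and exposes the discrete-time form
(T/2)·E[(exp(Δγ) − 1)‖ε − ε̂‖²]; on a 1-D linear-Gaussian toy the latter
matches an independent Gaussian-chain KL oracle (posterior moments rebuilt
from logistic algebra, expectation by Gauss–Hermite quadrature) and is
numerically nonincreasing in T toward the continuous value, as VDM theory
requires. Time points are antithetic (stratified): t_i = frac(u0 + i/n),
computed in index space so the exactly-one-per-bin property survives
floating-point rounding at bin boundaries. The reconstruction term is the
Bernoulli negative log-likelihood in stable logit form
softplus(l) − x·l; the "mean squared error" of the objective lives in
ε-space inside the diffusion term. The differential loss takes forward
finite differences on the common (H−1)×(W−1) grid and averages the squared
gradient disagreement; constants shift out. The total is a weighted sum
with nonnegative weights, all defaulting to 1.0; the weighting that produced
any externally reported single numbers is not derivable from the available
description, so no attempt is made to reproduce specific loss magnitudes
from other training corpora.

Randomness is split from a single seed into named child streams
(reconstruction noise, then diffusion time/noise), so each term of a
breakdown is individually reproducible.

## Sampling

Ancestral sampling draws z_1 ~ N(0, I) and repeatedly applies
x̂ = (z_t − σ_t ε̂)/α_t followed by a draw from q(z_s | z_t, x̂), with the
posterior variance scalable by a temperature (0 = deterministic trajectory).
The final image is the decoder's Bernoulli mean; binary pixel sampling is
available behind a flag. Correctness is checked on Gaussian data with the
closed-form optimal denoiser: at T = 1024 the sampled z_0 marginal matches
the exact marginal's mean and variance within 4 standard errors of 10⁵
draws, and the Wasserstein-1 error is nonincreasing over T ∈ {8, 64, 1024}.
Two step-count presets exist, `fast` (T = 5) and `paper` (T = 20,000),
mirroring the two published regimes.

## Training

AdamW with decoupled weight decay (excluded from biases, enforced by a
parameter-inventory mask that tests verify) under
lr(step) = base_lr · warmup(step) · cosine(step): linear warmup 0→1 over
250 steps, cosine 1→10⁻⁵ over the run. The three published learning-rate
fragments (cosine "initial 1.0", AdamW 8×10⁻⁴, warmup "0.0 to 1.0") are
read as multiplicative schedule factors on the base rate — the only
composition in which all three ranges are meaningful. Where printed values
conflict (batch 1 vs 64, lr 10⁻⁴ vs 8×10⁻⁴), the defaults take the
architecture/optimizer-paragraph values (64, 8×10⁻⁴). Training is
stateless-seeded: the per-epoch shuffle and per-step loss randomness derive
from (seed, epoch) and (seed, step) seed sequences, which makes resuming
from a checkpoint bit-exactly equal to the uninterrupted run without
serializing generator state. Checkpoints are flat named-tensor archives
with optimizer moments, step counter, and configs embedded as JSON.

The smoke-scale study condition is 500 optimization steps on 200 seeded
16×16 phantoms with batch 16; at that size a run takes seconds on one CPU
and reduces the total loss by roughly 40% from its initial value, safely
past the ≥20% criterion the smoke test asserts.

## Synthetic phantoms

Each phantom composes (i) a smooth background, 0.22 + 0.16·y vertically plus
a gentle horizontal sine, (ii) two elliptical lung fields brightened by 0.45
with logistic-soft boundaries and ±10% seeded jitter of position and axes,
(iii) `rib_count` (default 7) darker sinusoidal bands at amplitude 0.12
masked to the lungs, and (iv) additive Gaussian noise (sd 0.02), clipped to
[0, 1] (clipping affects < 1% of pixels at the default noise). Defaults were
chosen once to caricature the gross statistics of a frontal chest
radiograph — bright lungs on a darker gradient with periodic rib shadowing —
and the default corpus size (1341) matches the size of the clinical corpus
the model targets. The phantoms deliberately lack anatomy (mediastinum,
clavicles, soft-tissue texture, pathology) and acquisition effects (scatter,
grid lines, exposure variation), so passing tests demonstrate that the
machinery — losses, optimization, sampling, reproducibility — functions, not
that the model captures real radiographic structure.

## Numerical choices and limitations

* Tolerances: exact identities at 10⁻¹²–10⁻¹⁰; quadrature comparisons at
  10⁻⁶–10⁻³; Monte-Carlo comparisons at 4 standard errors; MC-vs-quadrature
  KL at 3% relative with 2×10⁵ draws.
* Degenerate inputs: s = t transitions give exactly (1, 0); tiny negative
  variances from float cancellation near s ≈ t are clamped to 0; a flat
  (constant-γ) schedule zeroes the discrete diffusion loss.
* The deterministic-inverse reading of the reverse process is not
  implemented; only stochastic ancestral sampling through the Bayes
  posterior is, the single construction consistent with the forward
  process's Gaussian conjugacy.
* Dense architectures cap practical image sizes; convolutional stems are out
  of scope. Single-process execution only; no EMA, mixed precision, or
  distributed replication. Class conditioning is exposed as a
  conditioning-vector hook but untrained by default.
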