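# Methods

## Overview

The package identifies single-neuron dynamics from simulated data: a
ground-truth neuron model is driven by a designed applied current, the
resulting one-step pairs (state and current now → state at the next Euler
step) form a regression dataset, and a wavelet-frame network ("wavenet") that
is linear in its weights is fitted by regularized least squares.  Because the
frame is fixed a priori, training is a single linear solve with a global
optimum — no backpropagation, no local minima.

## Neuron models

Four models generate all data.  Their defining property for this study is the
physiological current interval 𝓘 that brackets the transition between
quiescence and repetitive firing; training currents sweep 𝓘 so the dataset
contains equilibria at every excitability level and limit cycles at every
attainable frequency.  The parameter sets below were fixed once, before any
identification experiment, by checking the quiescent/spiking boundary against
𝓘 (the observable contract for each model):

* **Morris–Lecar** (`morris_lecar`): the standard calcium/potassium model in
  its class-I excitability regime — C = 20 µF/cm², g_L = 2, g_Ca = 4.4,
  g_K = 8 mS/cm², V_L = −60, V_Ca = 120, V_K = −84 mV, gating constants
  (V1..V4) = (−1.2, 18, 12, 17.4) mV, rate φ = 1/15 ms⁻¹.  Firing onset is
  ≈ 37 µA/cm², inside 𝓘 = [20, 60] and below its midpoint.
* **FitzHugh–Nagumo** (`fhn`): dv/dt = v(v−a)(1−v) − w + I_app,
  dw/dt = ε(v − γw) with a = 0.1, γ = 0.7, ε = 0.02 (time in ms).  Onset of
  repetitive spiking ≈ 0.074, inside 𝓘 = [0.07, 0.09].
* **FitzHugh–Nagumo–Rinzel** (`fhn3d`): the 2D model plus a slow linear
  current, dy/dt = µ(c − b·v − y) with µ = 0.001 ms⁻¹ (≈1 s timescale),
  c = 0.034, b = 0.02, y entering the voltage equation additively.  The slow
  variable shifts effective excitability so that sustained firing starts
  inside 𝓘 = [0.05, 0.07] and adds the second timescale that makes this model
  harder to identify.
* **Pyramidal-type model** (`wang`): a (v, h, n) conductance model with
  instantaneous sodium activation m∞(v): C = 1 µF/cm², g_Na = 35, g_K = 9,
  g_L = 0.1 mS/cm², E_Na = 55, E_K = −90, E_L = −65 mV, gate rate factor
  φ = 5.  Rheobase ≈ 0.16 µA/cm², inside 𝓘 = [−3, 3].  Its spikes are much
  sharper than the polynomial models', which is why it integrates at
  dt = 0.005 ms.

Integration is explicit Euler at dt = 0.05 ms (0.005 ms for the pyramidal
model), the same grid on which the wavenet operates, so the learning target is
exactly the Euler one-step map.  A 500 ms settling run at the lower end of 𝓘
provides initial conditions, removing transient dependence.  A divergence
guard aborts with the step index if any state magnitude exceeds 10⁶.

Robustness experiments multiply selected parameters by (1 + ξ(t)) with
ξ ~ U[−ξ̄, ξ̄] redrawn at every integration step (ξ̄ = 0.01 by default): the
leak and potassium conductances for the conductance models, a and γ for the
FitzHugh–Nagumo family.  Noise is drawn from a seeded generator, so noisy
trajectories are exactly reproducible.  With the noise redrawn per step its
effect largely averages out in one-step prediction; it mainly perturbs spike
timing over longer horizons.

## Stimuli

*Stepwise*: `n_values` plateaus of `ΔT` ms, values i.i.d. uniform on 𝓘.
Defaults follow the testing protocol (50 plateaus × 100 ms) and the training
protocol (plateaus of 100 ms for as many values as the training duration
requires; the hyperparameter sweep uses 200 ms plateaus on [0, 0.1]).
Plateau arithmetic is exact: ΔT must be an integer multiple of dt.

*Oscillatory*: a mean-reverting stochastic process whose drift target
oscillates slowly, `dI = (1/τ)(I₀ + ν cos(ωt) − I) dt + noise`, discretized
by Euler–Maruyama; I₀ is drawn uniformly from 𝓘.  Per model (τ, ν, σ) =
(10, 10, 9.5) for Morris–Lecar, (10, 0.005, 0.0045) for both FitzHugh–Nagumo
models and (10, 1.5, 2.85) for the pyramidal model, with
ω = 1.2π·10⁻⁴ rad/ms shared.  Two choices here were genuinely open:

* **Units.**  Times are milliseconds throughout (τ = 10 ms, one cosine period
  ≈ 16.7 s, so a 5 s test sees a third of a modulation cycle).
* **Noise scaling.**  The relaxation is applied to the stochastic term as
  well (diffusion σ/τ), giving stationary fluctuations of sd σ/√(2τ) — about
  2.1, 0.001 and 0.64 current units for the three parameter sets, i.e. an
  order of magnitude smaller than the half-width of the corresponding 𝓘.
  Taking the printed σ as a bare diffusion instead would give stationary sds
  comparable to or larger than the half-width of 𝓘 for *every* model, parking
  the test current far outside the physiological interval most of the time —
  incompatible with the stated aim of probing the neuron around its
  bifurcation.  The bare-diffusion discretization remains available via
  `intrinsic_noise=False`.

## The wavelet frame

Scaling families: the quadratic spline (three parabolic pieces on [0, 3],
interscale coefficients p = (1/4, 3/4, 3/4, 1/4)) and the "bicubic" spline,
implemented as the cubic B-spline on [0, 4] with p = (1/8, 1/2, 3/4, 1/2,
1/8) — the next order of the same B-spline ladder.  Both satisfy the
refinement equation φ(x) = Σ pₙφ(2x − n) to below 1e−10 on a dense grid
(a test asserts this), and Σpₙ = 2 with vanishing alternating sum, so the
mother wavelets have zero mean.

One-dimensional family on [0, 1]: the support-rescaled scaling function is
displaced so that copy k is centred at 1 − k/(N_S − 1), k = 0..N_S−1
(N_S = 1 degenerates to the single centred copy).  Each displaced copy spawns
its own wavelet family ψ^(k)_{r,n}(x) = 2^{r/2}ψ_k(2^r x − n) with
r = 0..N_R−1 and n = 0..2^r−1.  All functions are identically zero outside
[0, 1]; the truncation slightly clips the outermost displaced copies, which
is the price of equalizing approximation power near the domain edges.

Multi-input frames take tensor products level by level: the scaling level has
N_S^{N_I} products; level r draws each factor from the N_S scalings or the
N_S·2^r wavelets of that level, excluding the all-scaling product, giving
N_S^{N_I}((1+2^r)^{N_I} − 1) functions.  Identity (linear bypass) terms attach
to every state/voltage input but never to the current input — the unique
convention consistent with the studied frame sizes (1002 = 2 + 125 + 875,
24579 = 3 + 24576, 7780 = 4 + 7776).  Wavelon ordering is deterministic:
identities, then levels in increasing r, lexicographic within a level.

Inputs are mapped affinely onto [0, 1] per channel.  State channels use the
training-data range expanded by 5% per side.  The applied-current channel in
the experiment pipeline instead uses the *stimulus design range*: 𝓘 widened by
the oscillatory amplitude ν plus three stationary standard deviations.
Activations vanish outside the normalization box, and the oscillatory test
protocol provably exceeds the training interval when its baseline is drawn
near an edge of 𝓘; anchoring the current channel to the protocol's design
range keeps the frame active over every current the tests can produce.  Rows
that still fall outside the box raise a warning and contribute only through
the identity terms.

## Training

The design matrix G (one row per integration step, one column per wavelon) is
built in contiguous row chunks (default 8192 rows, chosen to keep the chunk
cache-resident) and consumed immediately by BLAS rank-k updates, accumulating
A = GᵀG and B = GᵀY; G is never materialized, so memory is bounded by J² + the
chunk.  Chunking is exactly invariant: rows are independent, and a test
asserts bit-level agreement between chunk sizes.  The regularizer is
γ = μ·λ_max(A) with μ = 2·10⁻¹⁶ everywhere (λ_max from a dense symmetric
eigensolver); (A + γI)σ = B is solved by Cholesky factorization with a
least-squares fallback if dead (never-activated) wavelons make A numerically
singular — with the widened current channel some wavelons legitimately see no
training data and then receive zero weight.  All outputs share A; the
training mean-squared error per output is recovered from the accumulated
scalars (YᵀY − 2σᵀB + σᵀAσ)/N_E without a second data pass.

A note on conditioning: the frame is deliberately redundant, so A is
ill-conditioned and *unregularized* weights are not unique to machine
precision; predictions, which live in the column space, are stable.  Tests of
chunk invariance therefore use a moderate ridge, while solver-correctness
tests compare against an independent dense solve of the same system.

## Paradigms, prediction, indicators

Paradigm I: row m = (states[m−1], I[m−1]) → states[m]; one shared G, one
weight column per state variable.  Paradigm II: row m = (v[m−1], …,
v[m−n_lags], I[m−1]) → v[m].  The lag count is the *total* number of voltage
samples per row (n_lags = 2 for the 2D models, 4 for the 3D study), the
convention consistent with the 7780-wavelon frame.

Teacher-forced prediction evaluates ŷ = G(x_T)σ̂ with true states in every
row — this is the mode behind all reported scores, matching the explicit
test-evaluation formula; free-running (closed-loop) prediction is also
provided, feeding predictions back through the input or the lag buffer, with
a divergence guard at a configurable margin outside the normalization box.
The ground truth never re-enters a free run after initialization.

Indicators, computed over 5-second tests with the first 100 ms discarded:
(1 − r²) per variable (residual sum of squares over target variance);
un-centered normalized cross-correlation R(k) over a ±50 ms lag window,
with R(0) equal to the cosine similarity *bit for bit* (both use the same dot
product); spike detection by upward threshold crossings (threshold = midpoint
of the voltage range of a reference run at 75% of 𝓘, minimum separation
2 ms); ISI histogram overlap (Freedman–Diaconis bins on the pooled sample,
Σ min of the normalized histograms).

## Problem sizes and expectations

Default training durations are 200 s for the 2D models (the full-length
2500 s runs add nothing at the achieved error level — one-step scores are
already at the 10⁻⁸–10⁻⁶ % level at 20 s), 75 s for FitzHugh–Nagumo–Rinzel
and 46 s for the pyramidal model; the original durations (2500/375/230 s) are
available behind an explicit `full_scale` flag.  The full-size pyramidal
Paradigm I problem — 46·10⁶ rows × 24 579 wavelons ≈ 1.13·10¹² design-matrix
elements (~8 TB in float64) — is exactly what the chunked normal-equation
path is shaped for, but it is not run by default; its sizing arithmetic is
asserted instead.

Because the ground truth is itself the Euler map on the same grid, one-step
identification can be nearly exact; this says that the frame can represent
the map, not that a real neuron would be captured equally well.  What the
synthetic study does *not* emulate: measurement noise on the recorded
voltage, channel stochasticity beyond the 1% parameter dither, unmodelled
latent dimensions (except deliberately, in Paradigm II), and electrode/
hardware artefacts.  Paradigm II quantifies the cost of hiding the recovery
variables: its (1 − r²) is orders of magnitude above Paradigm I while cosine
similarity stays high — the qualitative pattern expected when the network
must infer hidden state from voltage history.

## Known limitations

* Free-running prediction accumulates one-step error and is fragile at the
  boundary of the normalization box: one predicted spike peak overshooting the
  trained voltage range kills every spline activation, leaving the bare
  identity map, which expands.  Over stepwise test currents free runs track
  the neuron essentially perfectly (cosine similarity ≈ 1, ISI overlap 1);
  under the oscillatory protocol, which parks the neuron in sustained
  spiking, the overshoot occurs within a few hundred ms even at the full
  desk-scale training duration.  The run aborts at the guard rather than
  extrapolating silently; teacher-forced prediction is unaffected.
* The spike-sharp pyramidal model needs the r = 1 wavelet level (24 579
  wavelons) for a faithful fit; the desk-scale default (46 s of training)
  exercises the pipeline but is not expected to match full-size accuracy.
* The bicubic family is the cubic B-spline; if a different "bicubic"
  construction was intended upstream, counts are unaffected (they depend only
  on N_S, N_R, N_I) but individual activations would differ.
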