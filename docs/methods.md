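# Methods

`relapath` studies how a learner with separate *representational* and
*relational* modules resolves a violation of a learned relational
expectation, and why small violations are absorbed by the relational module
while large ones are absorbed by the representation.

## The task

Order discrimination: a pair of 224×224 grayscale images, each showing
identical shapes on a 3×3 grid, described by five features (grayscale
color, number, size, grid arrangement, shape type).  One scalar feature —
the *predictive* feature, size by default — changes between the two images
by the signed rule parameter α, measured in normalized feature units so
that |α| = 1 is the maximal feasible difference.  All other features are
resampled per pair but identical within a pair.  The left predictive value
is uniform over the interval for which the partner value stays in range
(`[0, 1−α]` for α ≥ 0).  Training shows only correctly ordered pairs; at
test the agent must judge whether a presented pair is in the correct order.

Generator conventions that the underlying study leaves open and that we fix
once: size maps to an enclosing-circle diameter of 12–70 px (cell extent
≈ 74 px); color maps to a shape gray level of 0–0.78 on a white (1.0)
background so shapes never vanish; number ∈ {1..9} normalizes as (n−1)/8,
making predictive-number rules multiples of 1/8; the shape catalog is
{circle, square, triangle, star, cross}; the occupied cells of the two
images are nested prefixes of one random cell permutation per pair (so that
arrangement is as shared as possible when the number differs); rendering is
hard-edged (pixel-center test, no anti-aliasing), which makes every image a
pure function of its feature vector and seeds — bit-exact across runs.

## The agent

The representational module Z_w is a small CNN mapping the image
(replicated to 3 identical channels) to one scalar: conv(16, k2) → ReLU →
conv(32, k2) → ReLU → maxpool(4) → conv(32, k3) → ReLU → maxpool(6) →
linear(2592 → 1), all convolutions stride 1, padding 1.  The pooling
strides equal the kernel sizes (4 and 6); that is the only geometry for
which the documented 2592-dimensional flatten exists at a 224-px input
(224 → 225 → 226 → 56 → 56 → 9, and 32·9² = 2592).  The relational module
is a single trainable scalar θ encoding the expected representational
difference ΔZ = Z(right) − Z(left).

The pair loss is

    L(w, θ) = (ΔZ − θ)² + λ (ΔZ² + θ² − r²)² ,

whose ring term forbids the collapsed solution ΔZ = θ = 0; the global
minima are ±(r/√2, r/√2).  Defaults: λ = 4, r² = 0.1, plain SGD with a
single learning rate 0.004 for w and θ jointly, batches of 2 image pairs,
20 SGD steps per batch, 160 pairs per training phase.  The batch loss is
the *mean* over the pairs in the batch.  Weights and biases initialize
uniform on ±1/√fan-in; θ, a one-input unit, on ±1.  Order decisions compare
the loss of the presented order with its reverse; exact ties (a
measure-zero event) count as incorrect.

### Numerics of the CNN

No GPU/torch framework is assumed: the forward and backward passes are
written directly in numpy.  Activations live in channels-last, zero-padded
buffers whose rows are flattened so that each kernel tap is a contiguous
slice and a convolution becomes k² BLAS sgemm calls without an im2col copy;
elementwise stages (bias+ReLU, bias+ReLU+max-pool and their adjoints) are
fused numba kernels; everything is float32.  The backprop is verified
against central finite differences in the test suite.  One SGD step on a
2-pair batch costs ≈ 0.15 s on one CPU core, so a 160-pair phase
(80 batches × 20 steps) is ≈ 4 minutes — the binding constraint on every
experiment scale below.

## Protocols and pathway classification

Experiments are phase sequences: initial learning (+α), symmetric reversal
(+α → −α), general reversal (+α₁ → −α₂) and the shaping protocol
(+α → β → −α), each phase 160 fresh pairs.  After every batch a checkpoint
records θ; a 32-pair held-out probe from the current phase's rule supplies
the mean ΔZ and test accuracy on a configurable schedule (probing costs 64
encoder passes, so by default it is dense over the early learning window
and sparse afterwards; the first and last batch of each phase are always
probed).

Because the reversal flips the presentation order, the probe ΔZ flips sign
instantly while θ is continuous.  Classification compares the end of the
first phase with the end of the final phase, with the post-reversal sign
(−ΔZ at the end of phase 1) as the ΔZ reference: θ flipped with ΔZ kept is
*relational* adaptation, θ kept with ΔZ flipped back is *representational*;
agents whose two signs kept or flipped together are *excluded* (they fail
the task).  Probe means within 1e−6 of zero carry no usable sign; such
dead-zone hits count as "sign not kept" and are flagged on the outcome.
Agents whose phase-1 accuracy ends below 0.75 are flagged as failed
learners but are not silently dropped.

The relational fraction per cell is #θ/(#Z + #θ) with excluded agents
removed from both counts; its uncertainty is a Jeffreys binomial interval.
The fraction-vs-α curve is summarized by the decreasing logistic
1/(1 + e^{c(α−d)}) fit by unweighted least squares (initial guesses
c₀ = 10, d₀ = grid midpoint); the inflection ᾱ = d.  The reported 95% CI on
d is 1.96·SE(d), where the parameter covariance is recomputed with
per-point binomial standard errors taken from the fitted curve: the plain
residual-scaled covariance of a 7-point fit is badly miscalibrated
(≈ 67% empirical coverage in simulation, vs ≈ 95% for the binomial-aware
version; the point estimate stays unweighted).

## Reduced model

With scalar inputs and a one-weight encoder (ΔZ = wα) learning becomes the
gradient flow

    dΔZ/dt = α² [(θ − ΔZ) − 2λ(ΔZ² + θ² − r²) ΔZ]
    dθ/dt  =     (ΔZ − θ) − 2λ(ΔZ² + θ² − r²) θ .

Fixed points: the origin (unstable), the attractors ±(r/√2, r/√2) and, only
for λ > 1/r², an unstable anti-diagonal pair ±√((r²−1/λ)/2)·(1, −1);
stability is read off the analytic Jacobian's eigenvalues.  With λ = 0 the
quantity ΔZ + α²θ is conserved, giving the line-attractor endpoint
(α²θ₀ + ΔZ₀)/(α² + 1); from the post-reversal state this is
(r/√2)(α²−1)/(α²+1), so θ flips iff α < 1, and in the general
+α₁ → −α₂ case the endpoint sign is the sign of α₁α₂ − 1.  The flow also
has an exact α ↔ 1/α symmetry (swap the two coordinates and rescale time),
which pins the symmetric-reversal inflection of the *regularized* model at
exactly ᾱ = 1.

Integration uses `scipy.solve_ivp` (LSODA, rtol = atol = 1e−9) with a
terminal event at ‖flow‖ < 1e−8 and horizon 10⁶ time units.  The horizon is
larger than one would naively pick because for small α the slow manifold is
approached at rate ∝ α²λr²; 10⁴ time units leaves α ≲ 0.1 unconverged.
Post-reversal starts are (−(r/√2)(α₂/α₁), r/√2).  The inflection and the
pathway boundary are located by bisection on the terminal sign of θ (an
infinitely fine grid in the variable being scanned); the boundary constant
k in α₂ = k/α₁ is the least-squares solution of log α₂* = log k − log α₁
over a uniform α₁ grid on [0.25, 4], matching the linear axes of the
reference map.  At λ = 0.1 the boundary products α₁α₂ sit within ≈ 2% of 1
except at the smallest α₁ (≈ 0.77 at α₁ = 0.25), a real finite-λ effect;
the fitted k is ≈ 0.96-0.97 on uniform grids of 9-13 points.  Cells whose trajectory reaches
the horizon or lands on no attractor are labeled `nonconverged`, and
|α₁α₂ − 1| < 0.02 is reported as "boundary" rather than forced to a side.

## What the synthetic world does and does not establish

The stimulus generator *is* the study's data-generating process (the
original data are themselves procedural), so a green test is a statement
about this stated world: uniform feature marginals, independent nuisance
features, exact rule differences.  It does not probe natural-image
statistics, nor rendering conventions other than the declared ones; the
supplementary predictive features (color, number) are supported as
generator configurations but the headline runs use size.

## Scale reductions and known limitations

Without a GPU framework the CNN costs ~4 min per training phase, so the
stochastic claims are verified at drastically reduced agent counts: the
packaged checks train one agent per condition (α ∈ {0.1, 0.5, 1.0} plus one
reversal continuation), and `scripts/acceptance.py` trains 3 agents at
α = 0.5 (the reference design uses 100).  At these counts the accuracy and
ring-solution checks are sharp (the quantities concentrate tightly across
seeds), but fraction-type quantities carry binomial noise of order 1/√n.
Two claims are not verified at all in the packaged suite because no design
below hundreds of phases supports them — the ANN inflection ᾱ ≈ 0.34 and
the shaping curve ᾱ(β); their pipelines are implemented and runnable
(`relapath reproduce fig5a`, `relapath reproduce fig6`, ~10⁴ CPU-minutes at
the reduced "desk" presets), and their acceptance tests fail with an
explanation instead of skipping.  The reduced model, where the same
qualitative claims are exact and cheap, is verified in full.

Other limitations: the learner is passive (no stimulus manipulation); only
the constant-θ relational module is implemented; no optimizer variants,
schedules or early stopping; within-category adaptation multiplicity is out
of scope.
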