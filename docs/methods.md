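# Methods

## The optimizer

EAOO-GA minimizes `f : [LB, UB] ⊂ R^Dim → R` with a population of N
candidate positions over T iterations. The algorithm imitates three phases
of oat-seed dispersal; each iteration first draws fresh biomechanical
parameters

- seed mass `m = 0.5 r / Dim`, awn length `L = N r / Dim`, eccentricity
  `e = 0.5 r / Dim` (independent `r ~ U(0,1)` each, once per iteration),
- decay `c = 1 − (t/T)³`, deterministic, falling from 1 to 0 and shifting
  the search from exploration to refinement.

**Exploration (wind dispersal).** Each selected individual moves by
`W = (c/π)(2 r_Dim − 1) ⊗ UB` from an anchor that cycles with stride
`s = max(1, ⌊N/10⌋)` over the 1-based index: population mean when
`mod(i, s) = 0`, the incumbent best when `mod(i, s) = 1`, otherwise itself.
The stride rule keeps roughly 10 % of the population on each special anchor
for any N; with N < 30 the "self" branch disappears by construction, which
we accept as the integer-modulus reading of the stated rule.

**Exploitation.** Rolling uses an envelope
`A = UB − |UB · t · sin(2πr)/T|` and step
`R = (m e + L²) · U(−A, A)/Dim`; jumping uses
`B = UB − |UB · t · cos(2πr)/T|` and a projectile-style step
`J = 2 k x² sin(2θ)/(m g) · U(−B, B)/Dim · (1 − α)` with awn elasticity
`k = 0.5 + 0.5r`, length change `x = 3r/Dim`, launch angle `θ = πr` (one
scalar `r` per individual shared by k, x, θ, so a right-angle launch
cancels the jump exactly) and drag `α = e^{r'/T}/π ∈ [1/π, e/π]`,
`r' ~ U(0, T)`. Both moves land at
`X_best + step + c · Lévy(Dim) ⊗ X_best`. Because the Lévy term multiplies
`X_best` elementwise, it degenerates in any coordinate where the incumbent
best is exactly zero; we implement the update as stated and rely on the
other steps to move such coordinates.

**Lévy flights.** Steps are `0.01 · μσ / |ν|^{1/β}` per component with
`μ ~ U(0,1)`, `ν` standard normal and

```
σ = [ Γ(1+β) sin(πβ/2) / ( Γ((1+β)/2) · π · 2^{(β−1)/2} ) ]^{1/β},  β = 1.5.
```

This scale differs from the conventional Mantegna recipe, which has β where
the π stands and a Gaussian numerator; we treat the π form as the defining
variant and expose `mantegna_levy=True` as a documented switch to the
standard form (σ ≈ 0.4255 vs 0.6966 at β = 1.5). The undefined outer
exponent is read as 1/β, the only choice that makes the expression a scale
for a β-stable step. `|ν|^{1/β}` is used rather than the literal
`|ν^{1/β}|`, which is undefined for negative ν at non-integer 1/β.

**Genetic enhancement.** After the dispersal moves, two population-wide
passes run when `use_ga_operators` is on: differential crossover
(`V_i = X_r1 + F (X_r2 − X_r3)` with r1, r2, r3 distinct and ≠ i, binomial
crossover at rate CR with a forced coordinate `j_rand`) and non-uniform
mutation (per-coordinate probability Pm, reach
`Δ(t, y) = y (1 − r^{(1−t/T)^b})` toward the nearer bound chosen by coin
flip, which vanishes exactly at t = T and cannot leave the box). Every
candidate — dispersal, crossover or mutation — replaces its incumbent only
if its objective is no worse (inclusive greedy rule), so the best-so-far
history is monotone non-increasing by construction.

**Scheduling.** The original phase schedule is not fully specified, so each
individual independently explores with probability `p_explore = 0.5`,
otherwise rolls or jumps with probability `p_roll = 0.5` — both exposed in
the configuration and flagged as our reading of the equiprobable-outcomes
statement.

**Numerical choices.** All moves are clipped to `[LB, UB]` (boundary
handling is otherwise unspecified). The seed mass is floored at 1e−12 in
the jump denominator. Non-finite objective values are treated as +∞ and can
never be accepted. Best-fitness ties keep the earliest incumbent, which
makes behavior on plateau objectives (accuracy is piecewise constant)
deterministic: a warm-start point that already attains the optimum is
retained verbatim rather than drifting across the plateau. Gravity
`g = 9.81` and non-uniformity degree `b = 5` are conventional defaults, as
neither is specified.

**Defaults.** N = 50, T = 100, F = 0.5, CR = 0.9, Pm = 0.1, β = 1.5 —
the shared comparison protocol. The baselines use the same protocol with
DE F = 0.5 / CR = 0.7 and GA crossover 0.8 / mutation 0.1 / tournament 3
(arithmetic blend crossover, chosen because the coding is real-valued and
the crossover operator is otherwise unspecified; elitism of one).

## Ensemble weight search

The weight vector lives on the M-simplex but the optimizer works on the box
`[0,1]^M`; candidates are mapped by clip-then-normalize (negatives to zero,
divide by the sum, all-zero to uniform) before evaluation. This keeps every
optimizer unconstrained and makes the mapping idempotent. The initial
population is warm-started with the uniform point and the M one-hot
vertices, so the returned ensemble provably never scores below the plain
average or the best single model. Accuracy is the default objective (the
explicit fitness of the ensemble procedure); mean categorical cross-entropy
(probabilities floored at 1e−12) is provided as the alternative smooth
objective. Argmax ties resolve to the lowest class index, fixed and tested.

## Attention and explanation math

The SE block is implemented bias-free (`s = σ(W₂ δ(W₁ z))` shows no bias
terms); a flag adds biases. The bottleneck width is `max(1, ⌊C/r⌋)` with
reduction r = 16 by default so tiny fixture channel counts stay valid.
Grad-CAM consumes supplied gradient tensors — analytic gradients of linear
toy scorers in the tests — keeping the module free of any autodiff
framework; heatmap min-max scaling to [0,1] exists only in the PNG export
path, separate from the defining ReLU-combination formula.

## Preprocessing and balancing

Augmentation parameter ranges are enforced, not merely documented: rotation
beyond ±10° or translation beyond 10 % per axis raises. Rotation and
translation use bilinear interpolation with zero fill (standard for
CT-like grayscale); the blur uses a 5×5 kernel with the kernel-derived
automatic sigma `0.3·((ksize−1)·0.5 − 1) + 0.8 = 1.1` and reflective
borders so constant images are preserved exactly. SMOTE uses k = 5
same-class Euclidean neighbors (reduced to class-size − 1 for small
classes), fresh `λ ~ U(0,1)` per synthetic sample, and targets the majority
count; single-sample classes are rejected because interpolation is
undefined. SMOTE operates on whatever feature vectors the caller supplies;
the package does not prescribe an embedding.

## Synthetic data: what it emulates and what it does not

`generate_prediction_matrices` emulates softmax-style classifier outputs:
uniform labels, per-model correctness Bernoulli at the target accuracy, and
rows built as `sharpness · one_hot(target) + (1 − sharpness) · Dirichlet(1)`
with sharpness 0.7, which guarantees the intended argmax (sharpness > 0.5)
while keeping rows stochastic and noisy. A correlation knob makes models
share per-sample difficulty draws, because weighting helps most when errors
are decorrelated. What this does **not** emulate: calibration structure,
class-conditional error patterns, or the feature-level correlations of real
CNN ensembles — so passing tests demonstrate the optimization and fusion
machinery, not clinical performance. The published headline accuracies of
the imaging pipeline depend on trained backbones and CT data and are out of
scope by design; the package reproduces the two worked numeric examples
that are pure accounting (class balancing to 420 per class; the 1097-sample
manifest total) and checks everything else as properties.

## Problem sizes

The test suite and the acceptance script use 5 seeds on the 5-D sphere,
10 seeds on 10-D Rastrigin for the ablation, 120–300-sample scenarios with
2–3 models for the fusion checks, and a 1001-point grid as the exhaustive
simplex oracle at M = 2. These sizes make the full pipeline reproducible on
a single CPU in about a minute while leaving each check statistically
unambiguous (the ablation gap on Rastrigin is roughly an order of
magnitude).

## Known limitations

- The plain-AOO exploration/exploitation schedule is our Bernoulli reading;
  other schedules are possible and would change plain-AOO behavior (less so
  EAOO-GA, whose genetic passes dominate late convergence).
- The `X_best`-anchored exploitation steps cannot perturb a coordinate of
  an exactly-zero incumbent via the Lévy term (see above).
- Accuracy plateaus mean recovered weights are not unique; uniqueness
  claims in tests are about objective value and warm-start retention, not
  about the weight vector as such.
- No constraint handling beyond the box and the simplex-by-normalization
  mapping; no parallelism.
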