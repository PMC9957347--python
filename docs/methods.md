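# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic experiments do and do not show.

## Preprocessing

**Adaptive median filter (AMF).** The filter is decision-based: a pixel is
declared corrupted only if it equals the salt value (255) or pepper value
(0). Corrupted pixels are replaced by the *lower* median (even-count tie
rule) of the non-extreme values in the smallest centered window containing
any, growing 3×3 → 5×5 → … up to `max_window` (default 7). If even the
maximal window holds only extremes, the pixel is kept and a warning logged.
This preserves every undamaged pixel exactly — the property that motivates
the decision-based variant over a plain median filter, which rewrites
correct pixels and blurs edges. Windows must be odd and no larger than the
image (violations raise, naming the offending dimension). Float images in
[0, 1] are rescaled to the 8-bit range and back; impulse detection happens
on the 8-bit scale.

The defaults (initial 3, max 7) comfortably cover impulse fractions up to
~20%: the chance that an entire 7×7 neighborhood is extreme at p = 0.2 is
negligible, so unreplaced pixels essentially never occur in that regime.

**CLAHE.** Tiles default to an 8×8 grid with 256 histogram bins.
`clip_limit` is relative: the per-bin ceiling is `clip_limit × tile_pixels`
(default 0.01); clipped mass is redistributed uniformly over all bins, which
preserves the histogram total, so the CDF endpoint stays `tile_pixels` and
the classic mapping `round((cdf − cdf_min)/(n − cdf_min) × 255)` applies
unchanged. Pixels are remapped by bilinear interpolation between the four
surrounding tile mappings, with tile coordinates clamped so border pixels
use their nearest tile only; images that do not divide evenly are padded by
reflection for histogram computation. Degenerate (constant) tiles map
identically — checked *before* clipping, since redistributing a constant
tile's clipped mass would otherwise fabricate contrast. With one tile and an
infinite clip limit the procedure reduces exactly to global histogram
equalization, which the test suite verifies against an independently coded
oracle to within one intensity level.

**PSNR** uses peak 255 (integer) or 1.0 (float); identical images report
`inf` rather than a large finite number.

## Feature extractor

The network follows the DenseNet-BC design: stem (3×3 stride-2 conv to 2k
channels, BN, ReLU, 2×2 average pool), four dense blocks, transitions
(BN-ReLU-1×1 conv to ⌊θm⌋ channels, default θ = 0.5, then 2×2 average
pool), and a final BN-ReLU-global-average-pool producing the feature
vector. Each sub-block is BN-ReLU-conv1×1(4k)-BN-ReLU-conv3×3(k) with its
input being the concatenation of all earlier maps in the block. Bottleneck
width 4k and pre-activation ordering are the standard DenseNet-B choices.
The total downsampling factor is 32, so input sides must be multiples
of 32.

Two profiles ship: the reference profile, blocks (6, 12, 36, 24) with
k = 48 — 2·(6+12+36+24) = 156 sub-block convolutions and the canonical
2208-dimensional feature width, asserted in its construction record — and
the desk-scale default, blocks (2, 2, 2, 2), k = 12, 64×64 inputs,
48-dimensional features. The big profile is constructible and
arithmetic-checked; training experiments use the small one.

There is no autodiff framework behind this package: all layers are NumPy
with hand-derived backward passes (convolution via im2col/col2im, batch
norm, pooling, linear). Every analytic gradient is validated against
central differences at tolerance 1e-7 in the test suite. Parameters are
float32; He initialization.

**RMSProp** is implemented from its recursion — squared-gradient moving
average `G ← βG + (1−β) g⊙g`, step `Δθ = −α g / √(G + ε)` with ε inside the
root — with defaults β = 0.9, α = 0.01, ε = 1e-8. Training uses
cross-entropy on a temporary dropout (default 0.5) + linear head, batch
size 5, and this optimizer only. A non-finite gradient raises, naming the
parameter block. The reference training configuration (50 epochs) is the
default; the pipeline and tests run 3–5 epochs because the synthetic task
saturates almost immediately.

Which representation feeds the classifier is a design choice: the
global-average-pooled final activations (the penultimate layer), extracted
in evaluation mode with the running batch-norm statistics, so extraction is
deterministic for a fixed model.

## LS-SVM

With labels encoded ±1 (arbitrary two-class labels are mapped in sorted
order and stored in the model), the fit solves

    [0  1ᵀ     ] [b]   [0]
    [1  K + I/C] [a] = [y]

and scores with `f(x) = Σ aᵢ K(x, xᵢ) + b`. This label-target form is
algebraically equivalent to the Suykens classification formulation (system
matrix `yyᵀ∘K + I/C`, unit right-hand side, decision
`Σ αᵢ yᵢ K(x, xᵢ) + b`) via `aᵢ = αᵢ yᵢ`; we chose it because the first
KKT row then gives the clean invariant `Σ aᵢ = 0`, and the decision
function matches the multiplier-times-kernel form directly. Kernels: linear
`x·x'` and RBF `exp(−γ‖x−x'‖²)`.

Numerics: the bias row is eliminated and the SPD block `K + I/C` is solved
by Cholesky; on failure a 1e-12 diagonal jitter is added (logged) with a
dense-solver fallback, and a still-singular system raises with the advice
to reduce C. Up to three iterative-refinement steps on the full KKT system
push residuals to ~1e-12 even for ill-conditioned draws. Ties in `predict`
(score exactly 0) go to the class encoded +1. Doubling C never increases
the training squared slack — the standard less-regularization monotonicity,
property-tested over seeded datasets.

## Archimedes optimizer

State per object: position x ∈ [l, u], density and volume initialized
U(0, 1), and a scalar acceleration initialized by one uniform draw in the
mean bound range (the literal vector-bound initialization mixes units with
the density/volume ratios anyway; normalization absorbs all scale, so the
scalar-per-object reading is used and broadcast across dimensions).

Per iteration t = 1..tmax:

1. densities and volumes drift a uniform random fraction toward the best
   object's values;
2. TF = exp((t−tmax)/tmax) and d = exp((tmax−t)/tmax) − t/tmax are
   evaluated (both also defined at t = 0 for inspection);
3. accelerations update as `(den_ref + vol_ref·acc_ref)/(den·vol)` with the
   reference being a uniformly random object ("material") when TF ≤ 0.5 —
   the boundary counts as exploration — and the best object otherwise; a
   zero denominator receives a 1e-12 stabilizer, logged once;
4. accelerations are normalized affinely onto [0.1, 0.9] across the
   population (min → 0.1, max → 0.9; an all-equal population maps to the
   midpoint 0.5) and the *normalized* value is what each object carries
   into the next iteration's collision term;
5. positions move: exploration
   `x ← x + C1·r·acc·d·(x_rand − x)` with C1 = 2 and a random partner, or
   exploitation `x ← x + F·C2·r·acc·d·(T·x_best − x)` with C2 = 6,
   T = min(C3·TF, 1) (C3 = 2; the cap keeps the attraction target inside a
   meaningful range and is configurable), and direction flag F = +1 iff
   P = 2·rand − C4 ≤ 0.5 (C4 = 0.5). `r` is a fresh uniform vector per
   dimension. Out-of-bounds positions are clamped (reflection available).
6. fitness is evaluated (NaN → +inf, logged); replacement is unconditional
   and a best-so-far tracker provides the monotone history.

Reference values in steps 1, 3 and 5 come from a snapshot taken at the top
of the iteration, so within-iteration update order is immaterial. One
seeded RNG stream drives the run; draws occur in the fixed order
density/volume pairs, then material indices + accelerations, then per-object
position draws — making runs bit-reproducible. C3 = 2 and C4 = 0.5 follow
the original AOA formulation (the source description leaves them symbolic).

On the 5-dimensional sphere with N = 30 and tmax = 200 the median best
fitness over ten seeds lands around 1e-4 — well under the 1e-2 acceptance
bar and orders of magnitude below equal-budget random search (~5).

## Hyperparameter tuning

Search is on log₁₀ scale — C ∈ 10^[−2, 4], γ ∈ 10^[−4, 2] (RBF only; the
linear space is one-dimensional) — the standard parameterization for kernel
hyperparameters. Fitness is the *pooled* stratified k-fold misclassification
percentage (all held-out predictions counted in one ratio), k = 5 by
default; a class smaller than k raises with the advice to reduce k. Fold
assignment is seeded independently of the optimizer seed, so optimizer
reruns see identical fitness surfaces. Fitness values are cached on decoded
parameters rounded to 1e-9; an ill-conditioned fit inside CV scores 100%
rather than aborting the search. The winner is refit on all data. Nested
cross-validation — the rigorous way to get an unbiased generalization
estimate after tuning — is deliberately out of scope; the pipeline instead
evaluates on a held-out split that tuning never sees.

## Synthetic data

The image generator emulates exactly the properties the pipeline exercises,
and nothing more: a balanced two-class design (default 200 per class, 400
total, matching the reference study's size), classes separated by blob
texture statistics (class A: many small bright Gaussian blobs, radius
≈ 4 px, amplitude ≈ 0.9; class B: few large dim ones, radius ≈ 9 px,
amplitude ≈ 0.45), clean intensities confined to a low-contrast window
(default [90, 170]) so CLAHE has range to stretch, and independent
salt-and-pepper noise at a configurable fraction (default 10%, split evenly
between extremes). `null_image_config()` gives both classes identical
statistics — the no-signal control. It is not an MRI simulator: no
anatomy, bias fields, Rician noise or 3D structure, so a pass here shows
the machinery is correct and the pipeline can exploit texture/intensity
separations, not that it would reach any particular accuracy on clinical
images.

The feature generator draws two spherical Gaussians with means ±Δ/2 along a
random unit direction; at Δ = 6σ the Bayes error is Φ(−3) ≈ 0.13%, so a
tuned classifier at ≤ 1% CV error is operating near the optimum.

## Evaluation protocol

Metrics are computed per class — each class taken as positive in turn, as
two-class medical reports conventionally tabulate — and averaged:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), balanced accuracy (their
mean), F-score 2TP/(2TP+FP+FN), and MCC, all ×100 (MCC therefore lives in
[−100, 100]). A zero denominator yields NaN plus a warning, never a silent
zero. Each pipeline "run" is a fresh seeded stratified 80/20 split with
preprocessing, backbone training and tuning confined to the training
portion; the master seed derives the split/backbone/fold/optimizer seeds
(seed, +1, +2, +3), and the metrics JSON embeds a config digest and all
seeds so a run can be reproduced from its artifacts.

## Problem sizes

Desk-scale experiments use the small backbone profile on 64×64 images with
3 training epochs, 100 images per class for pipeline evaluations (five
seeded runs each for the easy and null conditions: 40 held-out images per
run gives the null band ±5% sampling noise on the 5-seed mean), AOA budgets
of 10 objects × 15 iterations inside the pipeline and 10 × 12 for feature
tuning, and the full N = 30, tmax = 200 setting for the sphere benchmark.

## Known limitations

- The backbone is CPU NumPy: fine at the desk scale, not meant for
  ImageNet-sized training. Pretrained-weight loading is not implemented;
  the reference-profile weights would have to come from elsewhere anyway.
- Tuned CV error is an optimistic estimate of generalization (tuning sees
  the folds); the held-out split in the pipeline is the honest number.
- The AMF assumes impulse values exactly at 0/255; sensor noise that
  saturates legitimately at the extremes is indistinguishable from
  corruption by construction.
- Metaheuristic benchmarks are stochastic; the sphere criterion is stated
  over ten seeds' median for that reason.
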