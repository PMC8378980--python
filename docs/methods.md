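# Methods

This note documents the models, conventions and design choices behind
`swarmseg`, in the order the pipeline runs.

## Shrinkage-factor PSO

The optimizer is a global-best particle swarm maximizing a bounded
objective. Each particle carries a position, velocity, personal best
(pbest) and shares a swarm-wide global best (gbest). The improvement over
plain inertia-weight PSO is a *shrinkage factor* P(n), a constriction-style
multiplier on the entire velocity update that decreases linearly from
`p_max` to `p_min` across the `n_max` iterations. Because the factor
multiplies the whole bracketed rule — inertia term included — the dynamics
reduce to classical constriction PSO at w = 1 and to plain inertia-weight
PSO at P ≡ 1 (the `optimize_standard` baseline).

Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `swarm_size` | 30 | particles; conventional for low-dimensional searches |
| `n_max` | 100 | iterations; ample for k ≤ 3 threshold search |
| `p_max`, `p_min` | 0.9, 0.4 | shrinkage schedule endpoints (dimensionless) |
| `inertia_weight` | 1.0 | w; exploration/exploitation balance inside the bracket |
| `c1`, `c2` | 2.0, 2.0 | cognitive/social acceleration |
| `v_max` | 20% of each dimension's range | velocity clamp per dimension |
| `stall_window` | 0 (off) | optional early stop on gbest stagnation |

Numerical conventions: random draws r₁, r₂ are per-dimension vectors;
boundary handling is clamp-to-bounds with the clamped velocity component
zeroed (particles do not push into walls); pbest/gbest update on strict
improvement only, so the gbest trace is monotone non-decreasing and ties
resolve to the earliest-seen candidate; all randomness flows through one
`numpy` generator seeded from the config, making every run bitwise
reproducible.

The objective contract deliberately admits `-inf` as an "infeasible
candidate" marker (needed by the threshold decoding below) while rejecting
`NaN` and `+inf` as evaluation errors. If every candidate a swarm ever
sees is infeasible the reported best is `-inf`; the threshold search
screens this case out beforehand.

## Kapur maximum-entropy thresholding

For a gray-level histogram with probabilities p_i, thresholds
t₁ < … < t_k split the levels into k+1 classes; class j with mass ω_j
contributes entropy −Σ_{i∈j} (p_i/ω_j) ln(p_i/ω_j) and the score is the
sum over classes (nats). Fixed conventions: a single threshold t puts
levels [0..t] in the lower class; 0·ln 0 ≡ 0; an empty class scores
`-inf` (infeasible) rather than 0, which forbids degenerate all-background
optima; ties break to the lexicographically smallest threshold vector.

Two search routes exist on purpose: an exhaustive enumeration (guarded at
10⁷ combinations) acting as a brute-force oracle, and the PSO search over
the continuous box [0, n_bins−2]^k with round-half-away-then-sort
decoding, duplicates decoding to `-inf`. The PSO route must and does
reproduce the oracle's score; the exhaustive route realizes the
lexicographic tie-break exactly, while PSO returns an arbitrary member of
a tied plateau. On histograms whose classes are separated by zero-mass
gray levels the Kapur score is constant across the gap, so the *score* is
the bit-exact comparison target and the *threshold* may differ within the
tie.

A histogram with fewer than k+1 occupied levels (e.g. a constant image)
makes every candidate infeasible and raises a degenerate-input error
before any search runs.

## Preprocessing and pipeline

Stage order: percentile contrast stretch → optional Gaussian smoothing →
entropy threshold search → binarization → connected components → area
filter. Each stage is independently toggleable. Conventions: stretch
windows default to the 1st/99th percentiles; binarization is strictly
greater-than (consistent with the class convention); components use
8-connectivity labeled in row-major first-encounter order; all integer
rasters round half-away-from-zero; Gaussian kernels are sampled,
normalized, truncated at 4σ with reflective boundaries.

Two defaults deserve explanation:

* **k = 2 thresholds.** The reference images contain three tissue
  intensities (background/cavity, myometrial band, placenta), so the
  pipeline separates three classes and takes the brightest as the target
  (binarizing at the largest threshold). A single threshold on a trimodal
  histogram tends to merge the band with the placenta. `n_thresholds=1`
  remains the right setting for plain two-class images and is the default
  of the lower-level `pso_threshold_search`.
* **Smoothing off by default.** With the lexicographic tie-break a
  threshold can sit directly at the upper edge of the mid-intensity class;
  on a smoothed image the blur halo around the bright region then leaks
  into the mask. The area filter already removes impulse-noise speckle, so
  smoothing is reserved (as a toggle, in its specified position before the
  threshold stage) for images with heavy noise between the modes.

Cross-validation ("50/50" = 2-fold, with a repeats parameter) shuffles
cases into folds of near-equal size, selects the cheap preprocessing
knobs — stretch percentiles and minimum region area, over a four-point
grid — on each training split by mean Jaccard, and scores the held-out
fold. PSO hyperparameters are never tuned per fold.

## Evaluation statistics

Jaccard is intersection-over-union with empty∩empty defined as 1.0
(perfect agreement on absence avoids 0/0). Sensitivity, specificity and
accuracy are proportions in [0, 1]; a zero denominator produces an
explicitly undefined metric with a reason, never a silent 0 — notably, a
cohort in which every case is disease-confirmed has no true negatives and
therefore no defined specificity.

The paired comparison of two modalities is McNemar's test on the
discordant counts b (A correct, B wrong) and c (A wrong, B correct):
(|b−c|−1)²/(b+c) with continuity correction (numerator floored at zero,
so b = c gives statistic 0, p = 1), or (b−c)²/(b+c) without; p-values
come from χ²₁. Continuity correction is the default, which makes the test
conservative: under a 50/50 discordance null its empirical rejection rate
at α = 0.05 sits around 0.03.

## Phantom generator

The generator emulates the geometry of an axial uterine MR slice, not its
physics: an elliptical myometrial band (ring between concentric ellipses,
mean 110), a cavity and background at mean 40, and a placental crescent
at mean 180 hugging the lower inner wall. `invasion_depth_fraction` d
sets how far the crescent protrudes into the band, with grade encoding
d < 0.2 adhesive, d < 0.8 implantable, d ≥ 0.8 penetrated; depths are
scaled so d = 0.8 reaches the serosal (outer) boundary exactly and deeper
values bulge past it, matching the clinical meaning of "penetrated".
Realism layers are a multiplicative second-order polynomial bias field
(amplitude as a fraction of intensity) and additive Gaussian noise —
additive rather than Rician, which is immaterial on 8-bit magnitude
exports at the tested σ. Cohorts jitter the center, semi-axes and band
thickness per case and draw grades multinomially.

What the phantoms do *not* model: real placental texture and
heterogeneity, partial-volume effects, k-space/MR acquisition physics,
motion, or 3-D anatomy. Passing phantom-recovery tests therefore
demonstrates that the pipeline recovers a known bright region under
noise and bias — not clinical-grade performance on patient images.

Paired reader calls are simulated with a Gaussian copula: each case draws
a correlated bivariate normal and modality M is correct iff its normal
CDF value falls below the case's marginal probability (sensitivity for
diseased, specificity for controls). Any correlation in [0, 1] is
feasible for any marginals; correlation 1 with equal marginals makes the
modalities agree case-by-case.

## Problem sizes and determinism

Reference experiment sizes, chosen to characterize behavior at desk
scale: 100 random 256-bin histograms for the oracle-agreement experiment
(swarm 30 × 100 iterations each); 20 phantoms per noise condition at
256×256; 2-fold cross-validation over 20 phantoms; 2000 simulated cases
for sensitivity recovery and 2000 Monte-Carlo replicates of 100 cases for
the McNemar null calibration. Every experiment is a pure function of its
seed.

## Known limitations

* Kapur's criterion maximizes within-class entropy, which on strongly
  unbalanced two-class images can place the threshold inside the dominant
  mode's tail rather than mid-gap; the k = 2 default plus the brightest-
  class rule sidesteps this for the three-tissue case.
* Multilevel search is practical for k ≤ 3; the exhaustive oracle guard
  rejects larger k by design.
* The grade thresholds on invasion depth (0.2, 0.8) are fixed encodings;
  only their ordering is meaningful.
* The clinical-report module reproduces report *shape* (stratified
  metrics and paired tests); it ships no clinical data.
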