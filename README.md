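# swarmseg

Particle-swarm maximum-entropy segmentation of MRI-like gray-scale images,
with synthetic placenta phantoms, Jaccard evaluation and paired
diagnostic-accuracy statistics.

## The problem

Placenta accreta (PA) — abnormal adhesion or invasion of placental villi
into the uterine myometrium — is graded by invasion depth as *adhesive*,
*implantable* or *penetrated*, and prenatal MRI is increasingly used
alongside ultrasound to detect and grade it. Segmenting the placental
region out of a gray-scale MR slice is a thresholding problem: find the
intensity cut(s) that separate the bright placental tissue from the
myometrial band and the dark background. `swarmseg` implements that
pipeline end to end for researchers evaluating threshold-based placental
segmentation and for anyone comparing two diagnostic modalities on paired
case-level calls.

## The method

**Improved PSO (IPSO).** A global-best particle swarm maximizes a bounded
objective. On top of the classic inertia-weight update, a *shrinkage
factor* P multiplies the whole velocity rule and decreases linearly over
the run,

    P(n) = P_max − (P_max − P_min) · n / n_max,

so early iterations explore (P ≈ P_max) and late iterations refine
(P ≈ P_min). The velocity and position updates are

    v ← P(n) · [ w·v + c₁ r₁ (pbest − x) + c₂ r₂ (gbest − x) ],  |v| ≤ v_max
    x ← clip(x + v, bounds)

with defaults P_max = 0.9, P_min = 0.4, w = 1, c₁ = c₂ = 2, 30 particles,
100 iterations. A standard-PSO baseline (P ≡ 1) is included for
comparison.

**Kapur maximum-entropy thresholding.** Thresholds t₁ < … < t_k partition
the gray levels into k+1 classes; the score is the sum of within-class
Shannon entropies −Σ (p_i/ω_j) ln(p_i/ω_j). IPSO searches the continuous
box [0, 254]^k (round-then-sort decoding); an exhaustive brute-force
search serves as an independent oracle.

**Pipeline.** linear contrast stretch (percentile window) → optional
Gaussian smoothing → IPSO entropy threshold → binarization at the largest
threshold (brightest class = target) → connected components → area
filter. A 2-fold ("50/50") cross-validation harness tunes the cheap
preprocessing knobs per training split and reports Jaccard stability.

**Evaluation.** Segmentations are scored by the Jaccard index
J(X₁, X₂) = |X₁ ∩ X₂| / |X₁ ∪ X₂| against ground truth. Case-level
diagnostic calls yield sensitivity / specificity / accuracy, and two
modalities examined on the same cases are compared with McNemar's paired
chi-square test ((|b−c|−1)²/(b+c) with continuity correction, α = 0.05).

**Phantoms.** Because no imaging data ships with the package, a
synthetic-phantom module renders MRI-like uterine images (elliptical
myometrial band, bright placental crescent whose protrusion depth encodes
the grade, polynomial bias field, Gaussian noise) with exact ground-truth
masks, plus a Gaussian-copula simulator of correlated paired reader calls.

## Worked example

```sh
swarmseg phantom --n 4 --noise 5 --bias 0.1 --seed 7 --outdir cases
swarmseg segment --input cases/case000_img.png --seed 1 \
                 --out-mask case000_pred.png --report report.json
swarmseg eval --pred case000_pred.png --ref cases/case000_mask.png
```

prints

```text
wrote 4 phantom cases to cases
threshold(s) [33, 139] objective 9.414336 -> case000_pred.png
{"jaccard": 0.9869386976832872, "pred": "case000_pred.png", "ref": "cases/case000_mask.png"}
```

The swarm found the two-threshold Kapur optimum at gray levels 33 and 139
(on the contrast-stretched image, summed class entropy 9.414 nats); pixels
above 139 form the predicted placental mask, which overlaps the noiseless
ground truth with Jaccard 0.987 despite σ = 5 noise and a 10% bias field.
`swarmseg compare-pso --image cases/case000_img.png --report compare.json`
writes the IPSO and standard-PSO fitness traces for the same histogram,
and `swarmseg crossval --cases cases --folds 2 --repeats 5 --report cv.json`
runs the stability harness. Every command accepts `--manifest <path>` to
record a reproducible provenance manifest (config, seed, input hashes).

The same API is available from Python:

```python
import swarmseg as ss

case = ss.make_phantom(ss.PhantomParams(noise_sigma=5.0, seed=7))
result = ss.segment_image(case.image, ss.PipelineConfig(seed=1))
print(result.thresholds, ss.jaccard_index(result.mask, case.truth_mask))
```

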