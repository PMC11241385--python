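# Methods

## The grading problem

On cranial ultrasound of preterm infants, white-matter injury shows as
hyperechogenicity of the periventricular parenchyma relative to the
choroid plexus, which is normally the brightest intracranial structure.
The package quantifies that relation in two complementary ways: a scalar
echogenicity-difference score with fixed clinical cut points, and a
learned classifier over the joint appearance of the two regions.

## Stage 1: the delta-E echogenicity score

Images are 8-bit rasters (PNG/JPEG, TIFF read-only); single-channel
input is replicated to three channels, since ultrasound is achromatic
and replication leaves the colour machinery unchanged. Conversion to CIE
L\*a\*b\* assumes sRGB companding and the D65 reference white — the
universal default, and the convention against which the test-suite
oracle (a direct per-pixel evaluation of the published sRGB→XYZ→Lab
formulas) checks the library conversion. Regions of interest are
user-defined rectangles in 0-based half-open coordinates; a
`--one-based-inclusive` flag (and `RegionSpec.from_one_based_inclusive`)
accepts MATLAB-style bounds.

The score is computed *mean-then-distance*: each region is reduced to
its channel means (L̄, ā, b̄) and ΔE is the Euclidean distance between the
two mean triples — not the mean of per-pixel differences. On grayscale
input ā ≈ b̄ ≈ 0 (to a few 10⁻³; the conversion library's D65 white
differs from the matrix-implied white in the fourth digit), so the score
is effectively the lightness gap |L̄₁ − L̄₂|.

Grades: ΔE < 10 → Intensive, 10 ≤ ΔE ≤ 40 → Moderate, ΔE > 40 → Normal.
Both boundary points are assigned to Moderate; this is a documented
convention — the categorical rule as usually printed is ambiguous at the
cut points, and placing the closed interval in the middle band keeps the
partition exhaustive and exclusive. Zero is a valid score (identical
regions) and grades Intensive.

## Stage 2: the composite classifier

Each ROI crop is resized to 100 × 100 (bilinear, anti-aliasing off, so
the operation is bit-stable), stacked parenchyma-over-plexus into a
200 × 100 raw composite, and resized to the 100 × 100 × 3 network input.
The fixed patch order matters: swapping the roles produces a different
composite, and trained models are only comparable under one convention.

Architecture (channels-last, ~153k parameters):

| stage | output |
|---|---|
| input | 100 × 100 × 3 |
| [Conv 3×3 same → BN → ReLU → MaxPool 2×2/2] × 3 | 50²×16, 25²×32, 12²×64 |
| Conv 3×3 same → BN → ReLU | 12 × 12 × 128 |
| Dense → softmax | 3 |

Pooling uses floor division (25 → 12). All convolutions are same-padded
— the only scheme consistent with the preserved spatial sizes — and the
fourth block's kernel matches the first three. The engine is written in
NumPy (im2col + GEMM convolutions, float32); single-threaded it is
deterministic bit-for-bit given the seed, which drives He-style weight
initialisation and minibatch shuffling.

Training: minibatch RMSProp (cache ← 0.9·cache + 0.1·g²;
step = η·g/(√cache + ε)) on categorical cross-entropy, defaults
η = 10⁻³, decay 0.9, ε = 10⁻⁸, batch 16, at most 200 epochs. The loss is
unstated in the source protocol; categorical cross-entropy is the
standard pairing with a softmax head. Divergence (non-finite loss)
aborts with a diagnostic. Data protocol: stratified 70/15/15
train/validation/test split (200 samples → 140/30/30) plus stratified
5-fold cross-validation, both seeded.

## Evaluation

Multi-class results are reduced per class one-vs-rest: TP is the
diagonal entry, FN/FP the remaining row/column, TN the rest. Metrics are
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
accuracy (TP+TN)/(TP+TN+FP+FN), F-measure = harmonic mean of precision
and sensitivity, and one-vs-rest AUC by the Mann–Whitney rank sum with
midranks for ties (equal to the all-pairs concordance fraction, which is
how the tests check it). The "Overall" row is the unweighted macro mean.
Zero denominators — possible in small CV folds where a class is never
predicted — return 0 with a warning instead of raising. Cross-validation
aggregation reports mean and sample sd (n−1) per metric per class, with
the overall column aggregated from each fold's macro mean.

Two quantities in the reference model's published table are *not*
reproducible from its own confusion matrix under these definitions: the
per-class accuracy column, and the Moderate-row specificity (91.25%
printed vs 93.75% implied at equal class sizes; the accompanying prose
swaps the Moderate/Intensive specificities, consistent with a
transposition). The published overall specificity (93.08%)
likewise is not the macro mean of its per-class entries. The package
computes the standard definitions and does not reverse-engineer the
discrepant entries; the printed per-class F-measures also carry a
0.01-level rounding slip relative to exact harmonic-mean arithmetic
(91.23 vs 91.22, 86.23 vs 86.22), which the acceptance tests note by
asserting the exact values tightly and the printed ones at 0.02.

## The phantom generator

What it emulates: pairs of achromatic speckle-textured patches whose
regional mean-lightness gap is controlled per class — plexus fixed at
L = 75, parenchyma offset by the class ΔE target (Normal 50, Moderate
25, Intensive 5; each > 2 jitter-sd away from the nearest cut point) with
per-sample Gaussian jitter (sd 2 ΔE units). Texture is multiplicative
gamma speckle (shape 60, mean normalised to 1 after Gaussian smoothing
with σ = 1.5) applied to the linear luminance implied by the target
lightness, then sRGB-encoded and quantised to 8 bits. The generator is
calibrated purely to the ΔE bands because the score is the only image
property the grading consumes.

What it does not emulate: anatomy (ventricles, cyst formation), probe
geometry, attenuation, depth-dependent gain, repeated measures per
subject. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the stated separations are recoverable —
not that the published real-data accuracy transfers to clinical images.

Configurations whose bands would overlap the cut points within two
jitter sd are rejected at construction. Heavier speckle (smaller gamma
shape) biases and spreads the realized score — the lightness of a
mean-one multiplicative texture is concave in intensity — so
label-recovery degrades monotonically under speckle stress, which the
suite checks.

## Numerical and design choices

- **Composite geometry.** "Stacked side by side" is resolved as row-axis
  stacking producing 200 × 100 raw composites, the only reading
  consistent with the stated training dimensions; raw composites are
  then resized to the 100 × 100 × 3 input the architecture table fixes.
- **Resize:** bilinear, anti-aliasing off, edge mode; output pixel
  centres map to input coordinates (i + 0.5)·scale − 0.5. RGB output is
  rounded back to uint8; identity resizes return the input unchanged.
- **Argmax ties** in prediction break toward the lower class index
  (first occurrence), deterministically.
- **Paired statistics** use the before-minus-after convention (an
  improving, rising parameter gives a negative difference), sample sd,
  se = sd/√n, df = n − 1, two-tailed p. A zero-variance difference
  series is flagged degenerate with t and p undefined rather than 0/0.
  Skewness is the adjusted Fisher–Pearson estimator with its exact
  standard error √(6n(n−1)/((n−2)(n+1)(n+3))) ≈ 0.333 at n = 51; the
  cruder large-sample √(6/n) ≈ 0.343 rounds to the 0.34 printed in the
  reference tables, and the package deliberately reports the exact form.
- **Problem sizes.** The label-recovery checks run at 60 phantoms per
  class with a 20-epoch training budget, and the end-to-end demo
  defaults to 20 per class and 15 epochs with 5-fold CV: on these
  well-separated phantoms the classifier saturates well before the
  200-epoch default, which remains the configuration default for real
  data. These sizes are the package's chosen desk-scale study
  conditions and are recorded in each report.

## Known limitations

- The CNN engine is plain NumPy: adequate at this model size, but not a
  general training framework (no GPU, no autograd beyond the layers
  implemented, pooling restricted to non-overlapping windows).
- Batch-norm inference uses running statistics with momentum 0.9;
  very short trainings (a handful of steps) can leave them unconverged,
  visible as a lag between training and validation accuracy.
- ROI placement is manual by design; no segmentation or registration.
- Only CIE76 is implemented — the cut points are defined on that scale,
  so perceptually "improved" colour-difference formulas would not be
  drop-in comparable.
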