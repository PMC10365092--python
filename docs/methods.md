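# Methods

## Problem and model

White-matter tracts — anatomically defined fiber bundles such as the
corticospinal tract — can be segmented directly from diffusion-weighted MRI
(dMRI) by a convolutional network, but a clinical user also needs to know
*when not to trust* a segmentation. This package implements a pipeline
that (1) represents the dMRI signal in a rotation-aware spherical-harmonic
(SH) basis, (2) trains a multi-label 3D U-Net on that representation,
(3) draws stochastic segmentations at test time, and (4) calibrates the
volume uncertainty those samples imply.

### SH signal representation

A single shell (default b = 2000 s/mm²) is selected from the acquisition,
divided voxel-wise by the mean b0 image, and projected onto the real
even-degree SH basis up to degree `lmax = 4` by linear least squares
(no diffusion model is fitted). Even degrees suffice because the dMRI
signal is antipodally symmetric; the basis has (lmax+1)(lmax+2)/2 = 15
functions, ordered l = 0, 2, 4 with m = −l…l, orthonormal on the sphere.
Outliers are clamped per coefficient channel to the in-mask [5th, 99th]
percentile interval (linear interpolation between order statistics;
per-channel because channel magnitudes differ by orders of magnitude).
Percentile clamping with interpolated order statistics is idempotent only
up to the gap between neighboring order statistics at the cut points; the
test suite checks re-application changes values by less than 2 % of the
clamped range.

A clinical-quality acquisition is emulated by reordering gradient
directions so that every truncation prefix stays well spread on the
half-sphere (greedy electrostatic-repulsion ordering with antipodal
symmetry, deterministic index tie-breaks) and truncating to 45 directions
plus a proportional share of b0 frames.

### SH-consistent rotation

Rotating an SH image spatially without rotating each voxel's coefficient
vector breaks the link between fiber orientation and signal. Augmentation
therefore applies the same rotation twice: the grid is resampled
(trilinear for coefficients, nearest for masks, zero fill outside — using
`grid-constant` boundary handling so lattice-preserving rotations are
exact permutations), and every coefficient vector is multiplied by the
block-diagonal real-SH rotation operator. The operator is built per even
degree by solving `Y_l(u) D_l = Y_l(R^{-1}u)` on a fixed set of
well-spread directions; because the degree-l subspace is rotation
invariant this least-squares solve is exact to floating point, which the
sphere-sampling oracle in the tests confirms at 1e-8. Rotations are
extrinsic x-then-y-then-z; training draws the three angles i.i.d. uniform
on ±20°, the range also used by test-time augmentation. The rotation
center is the volume center in world coordinates.

### Network

A standard 3D U-Net: `depth` encoder blocks of
2 × (conv 3³, dropout, instance norm, leaky ReLU) followed by 2×2×2 max
pooling, a bottleneck block, and a mirrored decoder with 2×2×2 transposed
convolutions and skip connections; a 1³ convolution head with independent
per-class logistic outputs (tracts overlap, so multi-label rather than
softmax). Dropout (r = 0.25) lives in the encoder blocks only and can be
re-enabled at inference. Weights are He-uniform initialized from a seed.
The network is implemented directly on numpy arrays with hand-written
backpropagation (im2col convolutions in float32); a full-scale profile
(depth 4, 32 base filters, 15 → 72 channels) is expressible, and a
desk-scale profile (depth 2, 16 base filters, 16³ patches) is what the
tests train. Gradient correctness is verified against central differences
in float64.

### Training

The loss is class-weighted binary cross-entropy: per class,
w_n = max(C)/c_n where c_n counts positive voxels over the training set,
so the largest class has weight 1 and rare tracts count more; the class
sum is divided by N. The training loop optionally divides by the voxel
count J (on by default in the loop) so the loss scale does not couple the
learning rate to patch size; the un-normalized form is the default of the
standalone loss function. Probabilities are clipped to [1e-7, 1−1e-7].

Each epoch visits every subject once in random order; each visit draws a
fresh rotation (applied jointly to SH image, tract masks, and brain
mask), samples patches whose centers are uniform over the in-brain
voxels (zero-padded at borders), and steps SGD with momentum 0.9 and
weight decay 1e-6 on mini-batches of patches. The learning rate halves
every `lr_halving_period` epochs. The optimizer family, momentum, and
batch composition are deliberate package choices (only the rate schedule
and decay are externally pinned); everything is reproducible from one
seed. Full-scale defaults are 400 epochs, lr 1e-3 halved every 50, 50
patches of 64³ per visit; the desk-scale profile trains 90 epochs at lr
0.02 halved every 30 with 8 patches of 16³ in mini-batches of 2.

### Stochastic inference and uncertainty

Whole volumes are predicted by sliding windows (50 % overlap, uniform
averaging of overlapping predictions). Three stochastic modes draw T
probability volumes (T = 20 at full scale, 10 in the desk-scale tests):

* **TTD** — dropout active at inference (epistemic uncertainty);
* **TTA** — per pass, a random ±20° rotation of grid + coefficients,
  prediction, then the inverse spatial rotation so all passes live in
  subject space (aleatoric uncertainty); probabilities are
  orientation-scalars, so only the spatial rotation needs inverting;
* **Hybrid** — both simultaneously.

Each pass owns an RNG stream spawned from the master seed, so stacks are
bitwise reproducible and a longer run's first T passes equal a shorter
run's. The mean over passes is the prediction; the voxelwise population
SD (divisor T) is the uncertainty map, forced to exactly 0 where all
passes agree.

### Quantile-volume calibration

For each voxel the T pass probabilities define an empirical distribution;
its quantile at level k (linear interpolation of order statistics),
summed over voxels and scaled by the voxel volume |det A₃| mm³, gives the
soft volume V_k. Levels k ∈ {0, 1/T, …, 1} trace a monotone
quantile-volume curve. A ground truth volume's *coverage level* is where
the piecewise-linear curve crosses it (lowest crossing on plateaus).
Calibration fits, per tract on validation subjects, the empirical
quantile function of those coverage levels (knots at plotting positions
i/(n+1)) and uses it to remap nominal levels; remapped validation
coverage is then uniform on [0, 1].

Both coverage levels and the fitted map extend linearly beyond [0, 1]
along the end segments of the curve. This is the package's resolution of
a genuine design fork: a remap confined to [0, 1] can never report a
volume outside the raw [V_0, V_1] span, so a systematic volume bias
larger than the stack's spread would be uncorrectable and the calibrated
minimum volume difference could never improve. With linear end-segment
scaling, a biased cohort's calibrated curves recover both uniform
coverage (KS distance to uniform drops by ~3×) and a much smaller minimum
volume difference (~5×), as the simulation in the tests and acceptance
script measures. If every validation coverage level is identical the map
degenerates to a step; this is flagged and warned.

### Evaluation

Overlap metrics come from voxel confusion counts: Dice = 2tp/(2tp+fp+fn)
(1.0 with a flag when both masks are empty). Because printed definitions
of sensitivity/specificity vary between sources, both conventions are
implemented: "standard" (tp/(tp+fn), tn/(tn+fp)) is the default;
"as_printed" (tp/(tp+fp), tn/(tn+fn) — precision and NPV) is selectable,
and reports record which was used. Surface distances use a 6-connectivity
boundary (grid edge counts as background) and Euclidean distance
transforms in mm; Hausdorff is the max and ASSD the mean over the union
of both directed distance sets. Structure-wise uncertainty is the volume
variation coefficient VVC = σ_V/μ_V of per-pass binary volumes
(population SD; undefined when μ_V = 0), and its association with
segmentation error (1 − mean per-pass Dice) is measured by Spearman rank
correlation (exact rank-difference formula when tie-free, average ranks
otherwise). Residual maps are y − ŷ in [−1, 1].

## The phantom generator

Phantoms stand in for real acquisitions so the whole pipeline runs
without any download. Each tract is a radius-2.5-voxel tube around a
smooth curve crossing a 32³ grid — straight, C-shaped (bending in x-y),
or S-shaped (bending in x-z) — jittered per subject by ±1.5 voxels.
Distinct bending planes give the classes distinct local orientation
signatures, as real bundles have. The brain is an inscribed ellipsoid;
curves sit in its deep interior so tubes are never clipped. The DWI
signal is an axially symmetric single tensor:
S(g) = S₀ exp(−b[λ⊥ + (λ∥−λ⊥)(g·d)²]) with d the local curve tangent,
S₀ = 100, b = 2000 s/mm², λ∥ = 1.7e-3 mm²/s, λ∥/λ⊥ = 5 — giving tract
voxels strong degree-2 SH energy — isotropic λ = 0.9e-3 mm²/s elsewhere
in the brain, 60 well-spread directions plus 6 b0 frames, and Rician
noise (|signal + complex Gaussian|, SD 2 ≈ 2 % of S₀) by default with a
Gaussian option for analytic tests. Everything derives from one seed.

What the phantoms do *not* emulate: crossing fibers, partial-volume
mixtures, multi-shell schemes, susceptibility/motion artifacts, spatially
varying noise, or anatomical variability beyond control-point jitter.
Passing tests therefore show the pipeline's machinery is correct and that
the uncertainty/error relationship behaves directionally as expected —
not that full-scale accuracy numbers transfer to real brains.

## Desk-scale study sizes

The shipped test/acceptance study trains the depth-2/16-filter profile on
6 phantoms (32³, 3 tracts), evaluates Hybrid inference with T = 10 on 2
held-out phantoms, and runs the uncertainty sweep on 8 phantoms whose
noise SD rises from 0.5 to 12. Under these conditions held-out mean Dice
is ≈ 0.9 and Spearman(VVC, 1 − Dice) ≈ 0.9; both are recomputed from
scratch by `scripts/acceptance.py`.

## Numerical choices and edge cases

* SH fits refuse rank-deficient designs (condition number > 1e8) and
  fewer directions than coefficients.
* b0 threshold 50 s/mm²; voxels with mean b0 ≤ 1e-6 normalize to 0 and
  are counted in a log message.
* Probability threshold 0.5 is inclusive (p = 0.5 is foreground).
* Duplicate (antipodally identical) gradient directions warn and break
  ties by input index.
* Zero-epoch training returns the initial model unchanged; non-finite
  loss aborts with epoch/subject/learning-rate diagnostics.
* Network compute is float32; gradient tests monkeypatch float64.

## Known limitations

* The numpy network is CPU-bound and desk-scale; the full 105-subject,
  72-tract study the method targets needs a GPU framework.
* Calibration assumes validation and test subjects share an error
  distribution per tract; a distribution shift (e.g. pathology) breaks
  the coverage guarantee.
* Level extrapolation is linear in the curve's end segments; far outside
  the observed range it is a first-order guess only.
* TTA's inverse mapping interpolates probabilities; thin structures a
  voxel wide can lose mass at high rotation angles.
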