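# Methods

`pigweigh` implements and compares two estimators of live pig body weight
from a single top-down 3D point cloud: a classical linear regression on the
2.5D projected volume, and a PointNet-style permutation-invariant deep
regressor that consumes the raw point set. Because the study data this
pipeline targets (top-down clouds of grow-finish pigs, 20–120 kg, camera
2.7 m above the pen floor) is not publicly available, the package ships a
synthetic generator with analytic ground truth, and every quantitative claim
made by the tests is a property of the method demonstrated on that generator
— not a reproduction of field results.

## Coordinate conventions

All coordinates are meters in the camera frame: z is distance from the
camera along the optical axis, increasing toward the floor, which is the
constant plane `z = L` (default `L = 2.7`). Height above the floor is
`L − z`. Clouds are ordered sequences; every filter returns a subsequence of
its input (order preserved, colors carried, no point invented), which is the
invariant the filter tests assert point by point.

## Preprocessing chain

The animal is isolated from a raw pen scene by four filters applied in
order:

1. **Depth band** — keep `z_min ≤ z ≤ z_max`; removes the floor (z ≈ L) and
   most wall structure. The band limits are data-dependent and must be
   supplied; there is no universal default.
2. **Polygon ROI** — keep points whose (x, y) falls inside a pen-specific
   polygon (boundary-inclusive; shapely `covers` predicate). Removes wall
   points that share the animal's depth range.
3. **Color segmentation** — convert RGB to BT.601 luma
   (0.299/0.587/0.114), threshold with Otsu's method over the 256-bin 8-bit
   histogram (smallest argmax of between-class variance on ties), and keep
   the side of the threshold holding the majority of points; exact ties go
   to the brighter class, because the animal images lighter than shadowed
   clutter. A constant-intensity cloud is returned unchanged with a warning.
4. **Statistical outlier removal** — remove points whose mean distance to
   their k nearest neighbors (default k = 20) exceeds the global mean by
   more than `std_ratio` (default 2.0) standard deviations; kNN queries via
   a KD-tree. The filter is deliberately not idempotent: removing points
   changes the statistics.

Two further operations support the models. **Random subsampling** draws
exactly n points (canonical n = 1500) uniformly without replacement, seeded;
an opt-in `pad` mode duplicates uniformly chosen points when a cloud is
smaller than n, since the network requires a fixed-size input. **Jitter
augmentation** perturbs each coordinate by an independent uniform draw in
[−a, +a] (default a = 5 mm) — uniform, not clipped-Gaussian, because the
training recipe specifies hard bounds.

**Head cropping** automates the manual neck cut used when computing body
volume (a lowered or raised head changes projected volume but not mass).
The cloud is projected on its first principal xy axis; a width profile is
built in 2 cm slices; the anterior 35 % of the axis on the end with smaller
mean width is declared the head end; the cut is at the minimum-width slice
(the neck) in that region, and everything anterior is dropped. This is a
deterministic proxy for visual inspection; it assumes a single animal with
the head narrower than the torso, and it can only err by one slice width at
bin boundaries (the mirrored-cloud test bounds this).

## 2.5D projected volume and the linear baseline

Points are binned on a regular xy grid (default step 1 cm) anchored at the
cloud's (min x, min y) corner with half-open cells; each cell takes the
**maximum** height above the floor of its points; empty cells are zero, not
interpolated; volume is `step² · Σ heights`. Points below the floor are an
error rather than being clamped — upstream stages are responsible for not
producing them.

Two numerical properties of this estimator matter and are tested rather than
hidden:

* **Max-rule bias.** On a curved surface, the per-cell max overestimates the
  cell-mean height by ≈ `c · step · |∇h|`, so the total volume carries a
  one-sided positive bias ≈ `c · step · ∫|∇h| dA`. For a hemisphere of
  r = 0.25 m at step 0.01 this is about +5 %, and it *grows* with sampling
  density (the cell max approaches the cell supremum). A flat-topped slab is
  exact. The bias is a property of the max rule itself, halves when the step
  halves, and is shared by any tool implementing the same rule.
* **Sparse-cloud distortion.** When a cloud has fewer points than the grid
  has footprint cells (a 1500-point cloud over a ~3500-cell adult-pig
  footprint), most cells are empty and the "volume" degenerates toward
  `N · step² · mean height`, which scales with body height rather than body
  volume. The weight~volume fit still correlates but loses linearity for
  large animals. The noiseless-control test therefore uses dense clouds
  (20 000 points) to isolate generator linearity from this sampling effect;
  the comparison experiment deliberately keeps 1500-point clouds for both
  methods, as the pipeline's canonical size.

The baseline itself is ordinary least squares of weight (kg) on volume (m³)
with intercept; `r² = 1 − SS_res/SS_tot`, `rmse = √(SS_res/n)` (population
form). For a univariate linear fit this r² equals the squared Pearson
correlation.

## The point-set regressor

Architecture (widths are the canonical PointNet sizes):

* optional **input T-Net**: a mini point network (shared layers 32-64-128,
  pool, dense 64-32) emitting a 3×3 transform, initialized exactly to the
  identity (zero final weights, identity bias), applied to the coordinates;
* **shared MLP** 64-64-64-128-1024: the same dense→batchnorm→ReLU block
  applied to every point independently;
* **channel-wise max pool** over points — the symmetric aggregation that
  makes predictions invariant to point order (exactly, since max is
  order-independent; the tests allow 1e-4 kg for float accumulation);
* **dense head** 512-256 with batchnorm+ReLU, then a single output unit
  with ReLU, so predicted weight is nonnegative by construction.

The feature-transform block of the original classification network is
omitted (and consequently no orthogonality regularizer is needed); the
classification top is replaced by the rectified scalar. `width_scale`
multiplies all widths (rounded, floor 4), letting tests run the identical
architecture at quarter width.

**Input featurization.** Each cloud is centered at its xy centroid and z is
replaced by height above the floor, but the cloud is *not* rescaled to the
unit sphere. This departs from the usual point-cloud classification recipe
on purpose: absolute body size is the weight signal, and normalizing scale
away would delete it.

**Training.** Adam at a constant 0.01 learning rate, MSE loss in kg², RMSE
tracked in kg; batches of 32; up to 1000 epochs with early stopping on
validation RMSE (patience 10) and restoration of the best-epoch weights
(when early stopping is disabled, final weights stand). The dataset is split
9:1 train:validation uniformly at random by cloud (not grouped by animal;
an animal-level split is available as an option). Jitter is applied to
training clouds only, redrawn every epoch; validation and test clouds are
never augmented. Batchnorm uses exponential running statistics (momentum
0.9) at inference, so prediction is deterministic and batch-independent.
The output bias is initialized at +10 kg so the rectified output unit starts
alive. All randomness flows from explicit integer seeds; training is
bit-reproducible for a fixed seed and thread configuration.

The implementation is numpy with hand-derived gradients (verified against
finite differences in development); the batchnorm+ReLU stages are fused
into numba kernels because at these shapes elementwise memory traffic, not
the matrix products, dominates wall time. A semantically identical pure-
numpy path runs when numba is unavailable.

## Synthetic herd generator

A standing pig viewed from 2.7 m above is modeled as the upper half of a
superellipsoid torso (half-axes: length 0.55 m, width 0.19 m, height 0.26 m
at the ~70 kg prototype; cross-section exponent 2.2–3.2) resting its cut
plane on the floor, joined through a narrowed elliptical neck to a
half-ellipsoid head (head 30–42 % of body scale, neck 14–22 %) that pitches
about the neck joint (lowered head ⇒ smaller projected volume, a property
the tests assert). Legs are omitted — invisible from directly above and
irrelevant to a 2.5D volume. Clouds are sampled one point per uniformly
drawn line of sight over the footprint, which is how a depth camera samples
a surface; points carry light pig-skin colors.

Ground-truth volume is a fine (2 mm) numerical integration of the analytic
height field, independent of the rasterizer under test. Weight labels follow
the premise that mass tracks volume: `weight = 1000 kg/m³ × reference
volume + N(0, 2 kg)`, with per-animal dimensions solved (cube-root scaling)
so reference weights span 20–120 kg evenly. All clouds of one animal share
one label while pose (yaw, pen offset, head pitch in [−0.5, 0.15] rad)
varies per cloud — the posture-invariance the deep model must learn and the
volume baseline degrades on.

Sensor artifacts emulate the two observed hardware failure modes plus
speckle: a sinusoidal depth displacement across the xy plane (default
amplitude 4 mm, 2 cycles/m, random direction and phase), deletion of all
points in randomly centered discs (default 2 chunks of 6 cm radius), and
isotropic Gaussian point noise (default 2 mm). Displaced depths are clipped
at the floor plane. The wave amplitude/frequency are declared plausible
values, not fitted to hardware: no quantitative characterization of the
artifact exists to fit.

What the generator does *not* emulate: articulated posture beyond head
pitch, ear movement, body-surface reflectance variation, occlusion by pen
furniture, multi-animal scenes, and the true allometry of pig growth
(weight is linear in volume by construction; an allometric stress mode is
the natural extension). Passing tests therefore demonstrate method
properties — permutation invariance, posture robustness relative to the
volume baseline, recovery of a known linear law — not field accuracy on
real animals.

## Evaluation protocol

Weight classes split at 55 and 90 kg with half-open intervals [0, 55),
[55, 90), [90, ∞); membership is decided by the *actual* scale weight.
Per-class r² is computed within-class (against the class's own mean), so a
globally accurate predictor can legitimately score near zero inside a
narrow class; per-class RMSE does not have this caveat. Classes with fewer
than two samples report RMSE only. The experiment orchestrator reserves a
cloud-level random test set, fits the (head-cropped, 1 cm grid) volume
baseline on all remaining clouds, trains the deep model on the same clouds
with its internal 9:1 split, and scores both on the identical test clouds.

## Problem sizes used by the tests and the acceptance script

The shipped comparison experiment uses 80 animals × 5 clouds (400 clouds:
350 fit, 50 test), quarter-width networks, and at most 60 epochs — sizes
chosen so the full two-method comparison completes in a few minutes on one
CPU while leaving the learning problem non-trivial. Under these conditions
the deep model typically reaches test R² ≈ 0.95–0.99 and roughly halves the
volume baseline's test RMSE; the ordering (deep model beats volume baseline
on pose-perturbed data) is the property asserted, over a majority of three
fixed seeds since stochastic optimization at this scale occasionally lands
badly.

## Known limitations

* The max-rule rasterizer bias and sparse-cloud distortion described above.
* The head-crop heuristic assumes one animal, head narrower than torso.
* Cloud-level (not animal-level) splits let clouds of one animal appear in
  both train and test sets; this mirrors the protocol being modeled, and
  the animal-grouped option exists for the stricter design.
* The numpy/numba training loop is single-process and CPU-oriented; it is
  sized for hundreds-to-thousands of clouds, not millions.
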