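# Methods

## Soft segmentation targets

Light-sheet images of NeuN-stained cleared cortex do not resolve cell
membranes, so binary masks are not a meaningful training target. Instead
each annotated soma center becomes a unit-peak 3-D Gaussian,
`t(v) = max_i exp(−‖v−c_i‖² / 2σ_i²)`, and the network regresses this
field under binary cross-entropy with a sigmoid head.

The width rule is `σ_i = clip(d_i/κ, 1, 3.5)` voxels with `d_i` the
distance to the nearest other center. The published description fixes only
that σ depends on nearest-neighbour distance, is bounded in (1, 3.5), and
that hard instance labels are produced by thresholding the soft mask at
0.006; the constant `κ = 2√(2 ln(1/0.006)) ≈ 6.398` is this package's
choice, made so that two equal-σ cells at distance `d` have exactly
tangent 0.006-level support spheres (radius `3.199 σ` each) — the fixed
0.006 instance threshold is then consistent by construction. Overlapping
Gaussians are combined by voxel-wise **maximum**, not sum, preserving the
peak-1 normalisation the sigmoid/BCE head expects. A per-axis anisotropy
hook exists but defaults to isotropic (acquisition is 3.6 µm isotropic).

Instance labels use 26-connectivity: discretised sphere shells touch
diagonally, and 6-connectivity would split them. Plane-wise stitching for
2-D models links objects in *consecutive* planes only, merging at IOU >
0.3 with transitive closure by union-find; among several candidates the
highest IOU wins, ties to the lowest label.

## Network

A 3-D residual UNet: one 7³ stem convolution into a residual block, then
four encoder levels (three full-pre-activation residual blocks each —
norm → ReLU → conv — with 16 filters doubling per level), 2× max-pooling
between levels, a mirrored decoder with 2× transposed convolutions and
concatenated skips, and a 1³ sigmoid head. The full profile has 17.5 M
parameters. Choices the published description leaves open:

* **Normalisation**: group normalisation (8-channel groups). Training
  feeds one crop at a time, so batch statistics are unavailable;
  batch-independent normalisation keeps desk-scale training stable.
* **Optimizer constants**: SGD momentum 0.9, cosine decay from an initial
  rate with warm restarts. The schedule family is fixed by the design; the
  constants (lr 0.1, restart period in epochs) are package defaults.
* **Input normalisation**: per-volume percentile clipping (0.5–99.5) to
  [0, 1], absorbing the large slab-to-slab intensity shifts.

The engine is written directly in NumPy: convolutions as im2col matrix
products (z-chunked to bound memory), explicit backward passes per layer,
verified against finite differences in the test suite. It targets volumes
of tens of voxels per side on a CPU; the scaled-down profile (2 levels,
8 base filters, 16³ training crops, ~700 epochs) is the default for the
pipeline, with the full profile available behind `NetworkConfig()`.

Training loss cannot reach zero: with soft labels the BCE of a perfect
prediction equals the mean entropy of the target field (≈0.04–0.09 for
typical phantom densities). Progress is therefore judged by the excess
over this floor, and the capacity test in the suite uses a sparse target
whose floor is below 0.01.

### Tiled inference

Volumes larger than one forward pass are predicted in overlapping tiles.
Each interior tile face is trimmed by `overlap // 2` voxels (predictions
there are boundary-corrupted) and the remaining overlap is blended with a
linear ramp; faces flush with the volume border keep full weight. When the
trim exceeds the model's receptive field, any two tilings agree exactly
away from the volume borders; for the UNet (whose receptive field exceeds
practical overlaps) small residual seams remain, and group-norm statistics
add a tile-dependent component — both are negligible after training but
mean strict tiling invariance holds only for operators with receptive
field ≤ trim (this is how the suite tests the blending contract).

## Blob detection and tuning

The detector computes `G_{σs} ∗ f − G_{r·σs} ∗ f` (separable Gaussians,
reflective boundary, truncation 4σ), takes strict local maxima over 3³
neighbourhoods above a response threshold (plateau ties: first voxel in
(z, y, x) scan order), and greedily merges detections closer than a merge
distance, dropping the lower-response member so surviving detections stay
on response peaks (dropping, rather than averaging, is this package's
reading of "merged into a single one"). Sub-voxel refinement is omitted:
the evaluation criterion is 15 µm ≈ 4.2 voxels, so integer precision
suffices; "within one voxel" in recovery tests means the detection's
26-neighbourhood contains the true center.

The response threshold can be applied as an absolute cutoff (default) or
relative to the field's robust peak response (99.9th percentile) — the
DoG is linear, so the relative mode makes detection invariant to overall
prediction amplitude; the pipeline uses absolute thresholds, which
behaved better on tuned transfers in practice.

The four tunables (σ_small, ratio, threshold, merge distance) are
optimised against mean validation F1 by a tree-structured Parzen
estimator implemented in-package: uniform startup trials, good/rest split
at the 25 % quantile, per-dimension Parzen mixtures with
nearest-neighbour bandwidths, 24 candidates scored by the density ratio
l(x)/g(x). Default search space: σ_small ∈ [0.8, 4], ratio ∈ [1.1, 2.5],
threshold ∈ [10⁻⁴, 0.5] (log), merge ∈ [2, 12] voxels.

## Localization metrics

Matching is solved on the complete bipartite graph (no distance
pre-cutoff) by the Jonker–Volgenant solver in SciPy; the 15 µm criterion
applies only at classification, with strict inequality (a pair at exactly
15 µm counts one FP and one FN). The 6-voxel border frame removes
*points* (ground truth and predictions) whose any coordinate is < 6 or
≥ axis−6, dissolving affected pairs so the surviving partner counts as
unmatched — leaving a dangling matched partner would double-count.
Degenerate conventions: both sets empty after exclusion → P = R = F1 =
100 with a flag; exactly one empty → F1 = 0 with a flag. For comparison
against stereological annotation boxes (which exclude cells overlapping
the bottom-right border), predictions made on a larger volume are kept
inside the annotation box translated 3 voxels toward the origin,
half-open bounds.

## Stereology

The virtual optical fractionator places 100×100 µm² counting frames at
the nodes of a 2500×2500 µm² grid (uniform random offset for an
observer-independent design) with a 50 µm disector, and counts points in
half-open boxes — inclusion at the low edges, exclusion at the high
("bottom-right") edges — the unbiased counting rule. The reported density
is the sampling-fraction estimate
`ΣQ⁻ / (asf · hsf · V_region)` with `asf = frame/grid area` and
`hsf = disector/thickness`; it is exactly unbiased under a uniform grid
offset and coincides with `ΣQ⁻/(n_sites · frame_area · height)` (also
reported) for tiling designs, which the per-site form is edge-biased
outside of. The coefficient of error is reported only as the Poisson
approximation `1/√ΣQ⁻`, flagged as such. Layer aggregation uses the
sample (n−1) standard deviation.

## Phantom

The generator emulates what matters to this pipeline: blob-like somata
(Gaussian bumps, widths 5–8 µm, lognormal brightness, CV 0.25) from a
hard-core point process (default 15 000 cells/mm³ — mid-range for NeuN in
human cortex — with a 10 µm exclusion radius, about a soma diameter);
constant background with Gaussian read noise; sinusoidal stripes along
the illumination axis; lipofuscin-like speckles rendered *smaller*
(σ ≈ 1 voxel) and with a brighter, heavy-tailed amplitude than somata —
so a plain intensity threshold fails where scale-selective detection
succeeds; and per-slab affine gain/offset (0.6–1.6×) plus stripe/speckle
variation emulating inter-slab covariate shift. Published sources do not
quantify stripe amplitude or lipofuscin statistics; those defaults are
artifact choices, stated here once.

What the phantom does **not** model: optical PSF physics, refractive-index
mismatch, depth-dependent attenuation, vasculature, laminar boundaries
(only a density-vs-depth hook), or annotation error. Passing the pipeline
tests therefore demonstrates the machinery works under controlled
covariate shift, not performance on real tissue.

## Pipeline problem sizes

The end-to-end experiment uses three 64³ slabs (~0.012 mm³, ≈180 cells
each), the scaled-down network profile trained with 1400 single-crop
steps per training slab on 16³ crops (≈22 full passes over the crop
population) and Polyak/EMA weight averaging (decay 0.995) to smooth
single-sample SGD noise, leave-one-slab-out splits (train on the other
two slabs, tune the detector with 30 TPE trials on the training slabs'
predictions, evaluate once on the held-out slab). Prediction runs in 32³
tiles with 8-voxel overlap: tiled forward passes keep group-norm
statistics close to those seen on training crops, which measurably
improves held-out recall over whole-volume passes. These sizes are the
package's desk-scale defaults; the full-profile network and larger
volumes run through the same code paths.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; it is a reference
  implementation, not a production trainer.
* Group normalisation makes tiled inference weakly tiling-dependent (see
  above).
* The hard-core phantom at the default density leaves a small fraction of
  cell pairs within ~4 voxels; the integer-grid detector cannot always
  split them, so even on clean soft targets F1 saturates slightly below
  100 %.
* The fractionator's CE estimate is the Poisson approximation only.
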