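# Methods

## Measurement model

A tooth's mesiodistal angulation is defined as the orientation of the major
principal axis of its segmented pixel region, relative to the vertical image
axis. For a region with pixel coordinates (rᵢ, cᵢ) and centroid (r̄, c̄), the
second-order central moments are

    μ20 = Σ (rᵢ − r̄)²,   μ02 = Σ (cᵢ − c̄)²,   μ11 = Σ (rᵢ − r̄)(cᵢ − c̄)

and the orientation is θ = ½·atan2(2 μ11, μ20 − μ02), mapped into
(−π/2, π/2] so that θ = 0 for a region elongated along image rows (a
vertical tooth). This is the eigenvector direction of the 2 × 2 moment
matrix with the larger eigenvalue. Moments are computed directly from the
integer pixel coordinates; no smoothing or subpixel estimation is applied.

The horizontal upper and lower film borders serve as fixed reference lines
(maxilla and mandible respectively). Because both are parallel to the image
x-axis, the angle against the border is simply the complement 90° − |θ| of
the from-vertical angle; the package reports both, and the signed
from-vertical angle is the primary quantity.

**Sign convention.** Angles are signed: positive when the *occlusal* end of
the axis deviates toward increasing column index. The raw moment angle is
measured at the downward (increasing-row) end of the axis, so it is negated
for mandibular teeth, whose occlusal end points up. One consequence worth
stating explicitly: an in-plane rotation of the whole image by +r° shifts
maxillary signed angles by +r and mandibular signed angles by −r (the raw
from-vertical angle shifts uniformly by +r). Absolute values (`angle_abs_deg`)
are emitted alongside, and the agreement layer has an `absolute` switch,
since signed-vs-absolute reporting conventions vary.

## Apical exclusion

Root apices frequently curve (dilaceration), so the apical region can pull
the principal axis away from the clinically meaningful cervical–middle
direction. The pipeline therefore:

1. computes an initial θ on the full region;
2. projects every pixel onto the axis unit vector, with the sign fixed so
   the vector points down the image — maxillary apices then sit at the
   *minimum* projections, mandibular apices at the *maximum*;
3. removes the apical 22 % of the projection extent (inclusive boundary:
   pixels exactly at the cutoff are retained, making fraction 0 the exact
   identity);
4. recomputes θ on the retained pixels for the reported angle.

The initial (full-region) axis is used for the projection; only the final
angle comes from the trimmed region. The 22 % default (`apical_fraction`)
is a parameter; values in [0, 0.5) are accepted. The hooked-root phantom
experiments in the test suite quantify the step's value: with a 30° hook on
the apical 20 % of the shaft, the trimmed estimate recovers the shaft angle
to well under 1°, while the untrimmed estimate is biased by several degrees.

## Instance extraction and degeneracy

Connected components use 8-connectivity (robust to thin diagonal necks in
rasterized roots). Per class, only the largest component is kept — smaller
fragments are logged and dropped — and components below `min_pixels`
(default 50; a real tooth at 512 × 1024 is far larger) are discarded.
Isotropic regions (μ20 = μ02, μ11 = 0, e.g. a square) have no defined
principal axis: they yield angle 0 with `degenerate_flag` set rather than an
error, so batch runs never abort. Regions with fewer than 3 pixels raise.

## Agreement statistics

ICC estimates come from the two-way ANOVA decomposition (MSR between
subjects, MSC between raters, MSE residual):

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n)
    ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE)

ICC(2,1) (two-way random, absolute agreement, single measures) fits
examiner-reliability questions; ICC(3,1) (two-way mixed, single measures)
fits automated-vs-manual comparison, where the algorithm is a fixed
instrument. 95 % CIs use the exact F-distribution method, two-sided, with
Satterthwaite degrees of freedom for the absolute-agreement form.
Interpretation bands: < 0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good,
> 0.90 excellent; shared boundaries fall to the lower band (0.90 → good),
except 0.50 itself, which is moderate (poor is strictly < 0.50). A table
with zero total variance returns ICC 1 with a degenerate interval and a
warning. The implementation is authored here from the mean squares and is
cross-checked in the tests against both an explicit sum-of-squares oracle
and an independent statistics library.

Bland–Altman uses the sample (n−1) standard deviation of the differences;
limits of agreement are bias ± 1.96 s. Proportional bias is assessed by OLS
of the differences on the pair means (slope t-test) — a standard choice
where no particular test is mandated. Dice is 2|A∩B|/(|A|+|B|), defined as
1 (with a warning) when both masks are empty.

Grouped error tables match records on (image_id, fdi_code), drop unmatched
rows with a log line, and report per-group MAE and ICC(3,1) for groups by
tooth type, arch, or side. Repeat-acquisition sensitivity summarises
tooth-wise |differences| by mean, empirical 95th percentile, maximum, and
the fractions exceeding 1° and 2°.

## Phantom generator

The generator emulates the input the pipeline actually consumes — a
full-dentition 33-class label map at 512 × 1024 — not the radiograph itself
(no X-ray physics, no grayscale synthesis, no crown anatomy). Teeth are
capsule-shaped shafts placed on two arch curves with a gentle occlusal
curvature; each tooth's ground-truth angle is its base-table angulation
(apices leaning distally, 1–5° by tooth position) plus Normal(0, 2.5°)
noise, clipped at ±2 SD so that neighbouring teeth remain disjoint. The
layout constants (arch rows, tooth spacing, shaft sizes, base angles) live
in an editable module-level table (`phantom.ARCH_LAYOUT`); they are
stylized, plausible values, not measurements from any dataset.

Apical hooks emulate dilaceration: with probability 0.3 a tooth's apical
20 % is drawn as a second capsule segment deflected by 10–30°, always
curving distally (the common direction of dilaceration; this also
guarantees hooked neighbours cannot intersect). Overlapping tooth specs are
a hard error — ground truth would be ambiguous otherwise.

Repeat acquisitions are emulated by an in-plane rotation (≤ 10°) and
optional horizontal shear applied to the label map with nearest-neighbour
resampling (preserving label integrity); truth angles are updated
analytically through the same linear map, so re-measuring a perturbed map
reproduces its perturbed truth. Teeth pushed fully out of frame are dropped
from the truth with a warning.

Defaults: noise SD 2.5° (typical between-patient angulation spread at a few
degrees), hook probability 0.3 (dilaceration is common but not universal),
hook angle 10–30° (pronounced enough to bias an untrimmed axis). These are
the generator's fixed study conditions, chosen once.

**What passing tests do and do not show.** The phantoms have sharp class
boundaries, no segmentation noise, no crown morphology, no overlapping
anatomy and no projection distortion. Recovery of ground truth within 1°
on phantoms validates the geometry and statistics code; it says nothing
about segmentation quality on real radiographs, where the upstream
segmenter's errors dominate.

## Numerical choices

- Label maps resample with nearest neighbour only (class indices are not
  interpolable); grayscale uses bilinear with per-image min–max
  normalization (a constant image normalizes to zeros with a warning).
- The class-index ↔ FDI bijection is class = 8·(quadrant−1) + position,
  shipped as a plain-text table (`labelmaps.DEFAULT_SCHEMA_TABLE`); any
  consistent bijection would serve, so the mapping is config, not code.
- Projection-boundary ties in the apical exclusion are retained
  (inclusive), which keeps fraction 0 an exact identity and makes the
  trimmed fraction of a discrete vertical shaft exact (a 100-row shaft
  keeps exactly 78 rows at fraction 0.22).
- Rasterization discreteness bounds the moment-based angle error at roughly
  0.25° for shafts ~300 px long; the test tolerances (0.5° equivariance,
  1° recovery) sit above that floor.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical label maps and CSVs.

## Problem sizes

The test suite and the acceptance script run batches of 50–214 phantom
images (1 000–4 280 teeth), each image measuring 20 posterior teeth — full
dataset scale for the record-count check, and comfortably large for stable
agreement statistics on synthetic data.

## Known limitations

- Single 2-D projection only: mesiodistal angulation in the film plane;
  no buccolingual information, no 3-D root reconstruction.
- The measurement is deliberately sensitive to head positioning (fixed
  film-border reference); the sensitivity analysis quantifies, not
  corrects, this.
- No segmentation model is included; label maps come from an external
  segmenter or the phantom generator.
- Third molars exist in the schema but are excluded from the default
  selection, matching common orthodontic practice.
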