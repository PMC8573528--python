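# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `sparsecap`, in the order the pipeline runs.

## Coordinate conventions

Right-handed head frame: +x toward the right ear, +y toward the nose, +z
superior. All positions are millimetres; angles are degrees at API
boundaries and radians internally. Spherical angles follow the
"inclination/azimuth" convention used by cap manufacturers: θ is measured
from the superior (+z) axis (θ = 0 puts an electrode at the vertex), φ from
+x toward +y. Vendor tables using other conventions must be mapped to this
one before loading; the packaged tables already are.

## Local frame construction

Six steps, in a fixed order:

1. translate all markers so the LPA/RPA midpoint is the origin;
2. rotate the nasion direction onto +y — implemented as the *minimal*
   rotation (axis = cross product of current and target direction). Any
   rotation satisfying the constraint differs only by a rotation about +y,
   which step 3 fixes, so the final frame is unique; minimal rotation is
   chosen because it is deterministic and order-stable;
3. rotate about y so RPA lands on +x (and LPA, its mirror, on −x);
4. orthogonality correction: hand-placed preauricular markers are rarely
   exactly orthogonal to the nasion direction. Each of LPA/RPA is rotated in
   the plane it spans with the Nz direction, preserving its norm, until its
   component along Nz vanishes. The applied angle (mean over LPA/RPA; they
   coincide for pipeline inputs, where LPA = −RPA exactly) is returned as a
   placement-quality diagnostic. The operation is idempotent and moves only
   the two preauricular points;
5. z-origin shift to the mean z of T7/T8/Oz/FPz, centring the origin in the
   head the way template coordinates assume. Because those four electrodes
   sit on the template equator, the shift vanishes on ideal geometry — and,
   since the four positions sum to zero, it vanishes under *any* rotation of
   an ideal cap, which is what makes exact parameter recovery possible on
   noiseless synthetic captures;
6. stem-offset removal: the IR marker centre rides 21 mm above the scalp
   (10 mm marker-to-base + 11 mm electrode height). The direction of the
   correction is not derivable from a single marker; we move each electrode
   marker radially toward the local-frame origin (consistent with the
   quasi-spherical scalp), after the z-shift so "radial" is defined in the
   final frame. The strategy is configurable (`radial` | `none`), and the
   correction is applied to electrode markers only — fiducial markers sit on
   skin, not on electrodes (a config switch extends it to fiducials).

Degeneracies (coincident LPA/RPA, nasion collinear with the LPA–RPA line,
preauricular direction parallel to nasion) are detected with a 1e-6
relative threshold and raise typed errors.

## Virtual positions

Cap misplacement is a rotation of the electrodes relative to the (anatomically
fixed) fiducials. With fiducials pinned, electrodes are rotated about the
origin by (1) the minimal rotation taking unit(T8−T7) onto unit(RPA−LPA),
then (2) a rotation about x zeroing Cz's y-component. A rotation about x can
zero only Cz's y-component; any forward/backward x-offset of the vertex
marker is physically meaningful (the cap sat off-centre) and is reported as
`residual_cz_x` rather than forced away. The map is idempotent, preserves
electrode pairwise distances, and rotation 2 cannot break rotation 1's
condition (the aligned T7→T8 direction is parallel to x, which rotations
about x fix).

Whether the original procedure used a single minimal-axis rotation or a
sequence of axis-aligned rotations for step (1) is not determinable from its
description; minimal-axis is used here and documented as the package's
choice.

## Head models and template projection

Radii come directly from virtual marker distances to the origin — sphere:
r = ‖Cz‖; ellipsoid: r_x = ‖T8‖, r_y = ‖FPz‖, r_z = ‖Cz‖. No least-squares
fitting to more electrodes is attempted: with five measured positions the
direct estimator is exact on ideal geometry and transparent under noise.
Projection places each template electrode at
(r_x sin θ cos φ, r_y sin θ sin φ, r_z cos θ), which lies on the model
surface by construction; with equal radii the ellipsoid reduces exactly to
the sphere.

Model comparison: per-electrode Euclidean distances to the virtual positions,
paired between models, two-sided Wilcoxon signed-rank test. Zero differences
are dropped (standard signed-rank practice); the null distribution is exact
for n ≤ 25 and a normal approximation with continuity correction above; if
every difference is zero the p-value is reported as 1 and the winner as a
tie. The winner is otherwise the model with the smaller median distance.
Note that for a single head the five paired distances bound the exact
two-sided p at 0.0625 (0.125 when the Cz pair ties, as it always does —
both models place Cz at distance ‖Cz‖); single-head comparisons are
direction indicators, and cohort-level inference should pool electrodes
across heads as the acceptance script does.

## Template angle tables

The packaged `ten_twenty_64` and `radial_128` tables are idealized versions
of the two standard cap families (10-20 layout; radially equidistant from
Cz), derived from published idealized montage coordinates with all
inclinations scaled by 90/92 so the T7/T8/FPz/Oz ring sits at exactly 90°.
They approximate, but are not, any vendor's proprietary specification. In
the 128-channel table the five channels that coincide with the 10-20 anchor
positions carry their 10-20 names so the sparse-marker protocol applies
unchanged.

## ERP pipeline

The package consumes *cleaned* epochs (filtering, re-referencing, ICA
artifact removal are upstream concerns of standard EEG toolboxes).

* **Epoching**: windows are half-open `[start, end)` with sample count
  round((end−start)/1000·fs) — a [−200, 800) ms window at 512 Hz is exactly
  512 samples, which is what makes the Bonferroni divisor 512. Baseline
  correction subtracts the per-channel, per-trial mean over [−100, 0) ms by
  default.
* **Rejection** (defaults ±75 µV, 10 SD): amplitude — any sample beyond the
  threshold on any channel; kurtosis — per-channel epoch kurtosis z-scored
  across epochs, epoch statistic = worst |z| over channels; probability —
  per-epoch joint log-probability under per-channel histogram densities
  (64 bins, Laplace-smoothed), z-scored the same way. The kurtosis/
  probability criteria mirror the common EEGLAB-style measures, whose exact
  formulas are not published; the histogram-based reading here is an
  approximation and is documented as such. Decisions and triggering criteria
  are returned per epoch.
* **Spatial interpolation**: per time sample, piecewise-linear barycentric
  interpolation over a 3-D Delaunay tessellation of the source electrode
  cloud (linear fields are reproduced exactly at interior points; the
  identity holds at source positions). Template points outside the convex
  hull take the nearest source electrode's value and are flagged — with
  only five sampling sites on a convex scalp this is the common case for
  surface template points, so the flag matters and callers should inspect
  `extrapolated_labels`. The same engine serves bad-channel interpolation
  (interpolate a removed channel's position against the remaining channels).
* **Mass-univariate comparison**: at each time sample, a two-sided paired
  t test across participants on actual minus template-interpolated ERPs;
  α is Bonferroni-divided by the number of *samples* only — channels are
  treated independently, so familywise control is per channel, matching the
  per-electrode reporting convention of ERP placement studies. Zero-variance
  time points (identical differences across participants) report p = 1 and
  are flagged.

## Synthetic data

`generate_head` emulates the acquisition: electrodes on a ground-truth
ellipsoid at template angles; fiducials at (±r_x, 0, 0) and (0, r_y, 0); cap
misplacement as a rotation of the electrodes about the head origin;
fiducial non-orthogonality as an in-plane rotation of LPA/RPA; the marker
stem as a radial outward displacement (the exact inverse of the pipeline's
correction); isotropic Gaussian jitter (default SD 0.5 mm, a well-calibrated
optical system); and an arbitrary rigid camera pose. At zero jitter the
pipeline inverts every perturbation exactly, which is the module's central
recovery guarantee.

`generate_erp_dataset` produces per-participant epochs as a sum of
Gaussian-in-time components with Gaussian spatial falloff (Euclidean, not
geodesic, distance from the focus electrode — chosen for determinism and
simplicity) plus white sensor noise. Participants share the deterministic
signal and differ in noise realizations. All randomness flows from one seed
through named, crc-derived substreams, so stages and participants are
independently reproducible.

What the generator does *not* emulate: non-ellipsoidal head shapes, cap
fabric deformation (non-rigid electrode shifts), spatially correlated EEG
noise, geodesic field spread, or between-participant anatomical and
amplitude variability. Passing recovery tests therefore demonstrates the
geometry and statistics are implemented correctly under the stated model,
not that an ellipsoid captures any particular head.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale problem sizes chosen to
make the statistical checks decisive while staying fast: 100 random rigid
poses, 200 noisy captures for radii recovery, 100 heads (500 pooled
electrode pairs) for the model comparison, and 1000 null replicates of a
5-participant, 512-sample comparison for familywise-error calibration. All
are deterministic given the seed. Stochastic bounds use explicit binomial
3·SE margins rather than tuned constants.

## Known limitations

* Radii from single markers inherit that marker's noise directly (no
  averaging); at 1 mm jitter the median radii error is ~0.9 mm.
* The ellipsoid is axis-aligned with the fiducial frame by construction;
  heads whose principal axes are tilted relative to the fiducials are
  fit only approximately.
* The 21 mm stem correction direction (radial) is an assumption; on a true
  ellipsoid the surface normal is not exactly radial, contributing a small
  systematic error that grows with anisotropy.
* Wilcoxon p-values on five paired distances per head are floor-limited
  (see above); use cohort pooling for inference.
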