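# sparsecap

Full EEG electrode montages from a sparse set of motion-capture markers —
and the statistical machinery to ask whether electrode-placement error
actually changes your event-related potentials.

## The problem

Mobile brain/body imaging (MoBI) labs already run an optical motion-capture
system alongside EEG. Placing an infrared marker on *every* electrode of a
64- or 128-channel cap is slow and artifact-prone, but a small subset is
cheap: five electrodes (Cz, FPz, Oz, T7, T8) plus the three anatomical
fiducials (nasion Nz, left/right preauricular LPA/RPA). `sparsecap`
reconstructs the remaining electrode positions from those eight markers:

1. **Fiducial-anchored frame.** Markers are translated so the LPA/RPA
   midpoint is the origin, rotated so Nz lies on +y and LPA/RPA on ±x, a
   small correctional rotation makes origin→LPA/RPA exactly orthogonal to
   origin→Nz (the applied angle is a cap-placement QC diagnostic), the
   origin's z drops to the mean z of T7/T8/Oz/FPz, and the 21 mm marker stem
   (10 mm marker base + 11 mm electrode height) is removed radially.
2. **Virtual positions.** Keeping fiducials fixed, electrodes are rotated so
   T7→T8 ∥ LPA→RPA and Cz lies in the x–z plane — undoing cap-placement
   rotation so measurements are comparable with template coordinates.
3. **Head models.** A sphere (r = ‖Cz‖) or ellipsoid (r_x = ‖T8‖,
   r_y = ‖FPz‖, r_z = ‖Cz‖) is fit from the virtual markers, and every
   remaining electrode is placed from the manufacturer-style angle table:
   x = r_x sin θ cos φ, y = r_y sin θ sin φ, z = r_z cos θ
   (θ = inclination from +z, φ = azimuth from +x toward +y). Model fits are
   compared with a paired Wilcoxon signed-rank test on per-electrode errors.
4. **ERP sensitivity.** Epoched EEG is baselined, artifact-rejected
   (±75 µV amplitude, 10 SD kurtosis/probability criteria), averaged, the
   scalp field is barycentrically interpolated from actual to template
   positions over a 3-D tessellation, and actual vs template-interpolated
   ERPs are compared with a per-timepoint paired t test, Bonferroni-corrected
   over samples (α = 0.05/512 ≈ 9.8e-5 for a 1 s, 512 Hz trial).

A synthetic-data module generates ground-truth ellipsoidal heads, realistic
capture perturbations (cap misplacement, fiducial skew, marker stems, camera
jitter, arbitrary camera pose), and multi-participant ERP datasets, so every
stage is testable by parameter recovery without any recorded data.

## Worked example

`examples/localize_synthetic_head.py` builds a ground-truth head with
ellipsoid semi-axes (75, 95, 90) mm, simulates an eight-marker capture with
5° cap misplacement, 2° fiducial skew, 21 mm stems and 0.5 mm jitter, and
localizes from the markers alone:

```
fiducial correction angle :   2.23 deg  (injected 2.0)
origin z-shift            :   0.48 mm
stem offset removed       :  21.00 mm
recovered ellipsoid radii : (75.11, 95.88, 89.01) mm  (truth 75, 95, 90)
actual vs virtual markers : median 9.5 mm [6.9, 11.4]  <- cap-placement error
sphere    model fit       : median 6.92 mm [5.84, 13.74]
ellipsoid model fit       : median 0.31 mm [0.26, 0.85]
model comparison          : winner=ellipsoid, Wilcoxon p=0.125
median error of the 59 estimated electrodes vs ground truth: 0.72 mm
```

The correction angle and radii come back at their injected values to within
the marker noise; the ellipsoid model fits an anisotropic head an order of
magnitude better than the sphere; and the actual-vs-virtual distance
quantifies how far the cap was rotated from its nominal pose.
`examples/erp_placement_sensitivity.py` and
`examples/marker_files_round_trip.py` walk the other two capabilities
(placement-error ERP statistics; exchange formats).

## Command line

The same workflows as shell commands, for batch use:

```bash
sparsecap simulate --seed 42 --noise-sd 0.5 --out-dir capture/
sparsecap localize --markers capture/markers.csv --angles ten_twenty_64 --out-dir out/
sparsecap erp-compare --epochs p0 --epochs p1 ... --actual actual.sfp --template tmpl.sfp
```

Built-in angle tables: `ten_twenty_64` (10-20 layout) and `radial_128`
(radially equidistant from Cz); any `label,theta_deg,phi_deg` CSV works too.
Positions are written as BESA-style `.sfp`, `.elc`, or CSV.

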