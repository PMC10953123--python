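# Methods

This note documents the models, numerical choices and validation logic of
the `compoundeye` pipeline, module by module, and states what the synthetic
generators do and do not emulate.

## Coordinate conventions

All physical 3D coordinates are (x, y, z) in micrometres with +x lateral
(azimuth 0), +y anterior and +z dorsal; voxel grids are stored (z, y, x) as
TIFF pages. Elevation is the angle above the equatorial plane
(`asin(z/r)`), azimuth the angle about the dorsoventral axis with anterior
positive (`atan2(y, x)`), both reported in degrees. Angles are computed in
radians internally and exposed in degrees everywhere, including the Nyquist
relation (passing radians there would change the answer by a factor of ~57,
so the optics interface is strictly degree-typed).

## Synthetic eyes

A synthetic eye is a set of plano-convex lens blobs (half-ellipsoids with
their flat face on the local tangent plane, bulging outward) voxelised on a
spherical cap of radius *R*. Two lattice modes:

* **Uniform** — spherical-Fibonacci seeding inside the cap followed by a
  spring/repulsion relaxation (a Lloyd-style local relaxation; exact
  spherical-Voronoi Lloyd is ill-posed on a cap because boundary cells are
  unbounded) toward quasi-hexagonal packing. The angular lattice constant
  follows from the cap solid angle Ω and lens count *n* via the hexagonal
  cell area: a = √(Ω / (n·√3/2)).
* **Profiled** — hexagonal rows on a lat-long patch whose row spacing
  follows a prescribed IO-angle profile of elevation (flat equatorial band,
  linear ramp to a peripheral value). This is the mode used to build acute
  zones (e.g. equatorial IO 5°, peripheral 15°); a density gradient cannot
  be imposed cleanly on a Fibonacci lattice.
* A 7-lens rosette (centre + hexagonal ring) is used when exactly seven
  lenses are requested; on a small enough cap its neighbour angles are
  equal to machine precision, which anchors the symmetry tests.

Facet diameters follow `base_diameter + azimuthal_gradient·azimuth`, with
an equatorial band shrink factor reproducing the band of smaller facets
along the eye equator. Centre jitter (`noise_sd`, µm) models lattice
irregularity; tiling feasibility is checked on the nominal lattice (an
infeasible request raises an error naming the maximum feasible lens count)
and jitter-crowded pairs then shrink locally rather than overlap, as real
facet lattices deform rather than interpenetrate. Default conditions are a
fly-scale eye: 600 lenses, R = 290 µm, Ω = 2.5 sr, 16 µm facets (IO ≈ 4°,
inside the 4–6° equatorial range typical of these flies), 10% band shrink,
1 µm jitter, 1 µm voxels (≈ 500×490×150 grid; unit tests use 2 µm voxels
for speed).

The truth table records, per lens: on-sphere centre, voxel centroid,
outward axis, diameter, length, voxelised volume, polar coordinates and the
mean angular distance to lattice neighbours (`io_true_deg`, neighbours =
points within 1.45× the nearest-neighbour distance).

What the generator does **not** emulate: partial-volume grey levels and
scan artefacts (volumes are ideal binary), lens shape variation beyond the
half-ellipsoid, inter-lens cuticle, and any deviation of optical axes from
the local surface normal (axes are exactly radial). Detector recovery on
these phantoms therefore demonstrates correctness of the geometry chain,
not robustness to segmentation noise in real scans.

## ODA-3D detection

1. **Surface fit.** Algebraic least-squares sphere through all lens-voxel
   coordinates (linear in centre and radius). A biquadratic height-field
   over the cloud's principal plane is fitted as well; auto mode keeps the
   sphere unless its RMS residual exceeds twice the height-field's (which
   rejects planar/saddle clouds where no sphere is meaningful).
2. **Projection.** Azimuthal-equidistant chart about the cap centre:
   chart radius = R·θ, with the signed radial offset preserved, giving an
   exactly invertible mapping (round-trip error < voxel size, asserted).
   The chart's tangential scale is sin θ/θ; the per-voxel area correction
   exposes exactly this factor so corrected footprint areas are unbiased
   out to the cap edge. (The raw, uncorrected chart area is ~17% compressed
   at θ = 60°, which is why the correction is applied rather than assumed
   negligible.)
3. **Clustering.** Lens spacing is estimated from the radial periodogram of
   the projected voxel-count image: the first spectral ring of a hexagonal
   lattice sits at f = 2/(√3·s). A prominent *interior* local maximum is
   required — blob or noise spectra decay monotonically from DC and
   correctly raise an error advising a manual `spacing_um` override. Local
   maxima of the Gaussian-smoothed image (σ = spacing/5, min distance
   0.3·spacing) seed a watershed restricted to occupied pixels, so every
   lens pixel receives exactly one label; sub-minimum lenses (default
   20 voxels) are dropped and logged.
4. **Metrology.** Volume = voxel count × voxel size³; cross-sectional area
   = distinct footprint pixels × pixel area × area correction; diameter
   = 2·√(A/π); axis = outward surface normal at the centroid blended 25%
   toward the lens's thinnest inertial axis (the normal dominates because
   axis noise enters IO angles directly; the inertial term lets genuinely
   skewed lenses pull away from the normal); length = extent along the
   axis (a config switch measures along the normal instead, since the
   choice is not uniquely determined by the source methods).
5. **IO angles.** Immediate neighbours = Delaunay edges of the projected
   centroids, discarding edges longer than 1.8× the median (spurious hull
   edges). Pairwise IO = angle between axes; `io_mean_deg` averages over
   the neighbour set; isolated lenses get NaN and are excluded from
   downstream medians.
6. **Surface area.** SA = Σ π(d/2)², assuming circular facets; mean lens
   area A = SA/N holds by construction.

Recovery at the default study conditions (600 lenses, 1 µm jitter): count
within ±1%, centroid error ≪ diameter/4, diameter MAE < 0.5 µm, median
IO-angle error ≈ 0.25° < 0.5°.

## Eye maps and slopes

Profiles divide a metric into evenly spaced bins spanning the observed
axis range (20 bins by convention) and report mean ± 3×SEM per bin; empty
bins keep count 0 and an undefined mean (never interpolated), single-lens
bins report zero error. Band statistics restrict to |orthogonal axis| ≤ 15°
by default (the equatorial band). Equator alignment is manual by default
(matching the source workflow); auto mode finds the tilt about the lateral
and anterior axes minimising the mean |elevation| of the smallest-decile
diameter lenses (grid search ±30° then Nelder–Mead) and refuses when facet
diameters have no detectable band (CV < 0.5%).

Azimuthal slopes are per-subject OLS fits of the unbinned per-lens metric
on azimuth (the binned-first alternative is noted as ambiguous in the
source; unbinned matches "regress … on azimuthal position"). Group
comparison is a two-tailed pooled-variance t-test (df = n₁+n₂−2, matching
the reported df = 10 for 6+6 eyes) with Cohen's d from the pooled SD;
Welch's correction is available by flag. A zero-pooled-variance contrast
with unequal means reports p = 0 with a warning.

## Allometry

Each outcome is fitted by OLS on [1, SA, species_dummy] on raw scales (the
source figures are linear in SA; log-log is available by flag). The species
contrast is the Wald t-test on the dummy coefficient, with the coded group
named explicitly so a label swap negates the contrast exactly. Quantiles
use linear interpolation (type 7). Degenerate designs (one species, equal
SA, species confounded with SA) are rejected. On synthetic cohorts
(n = 12, known slope and offset) estimates are unbiased to < 2% over 200
seeds and the dummy's null rejection rate is 5% (exact, as the t-test df
is correct).

## Psychophysics

Pipeline order is fixed: fold → baseline → normalise → window → bootstrap.
Folding averages leftward responses with the sign-inverse of rightward
responses (per fly and grating), cancelling constant directional bias
exactly; fold and baseline correction commute (both linear), which is
asserted as a regression test. Baseline = mean of the 0.1 s before motion
onset. The response window is 0.5–1.25 s after onset with inclusive bounds
(751 samples at 1000 Hz). Normalisation divides each fly's windowed means
by that fly's maximum signed mean (the maximum becomes exactly 1; negative
values are countersteering); flies with no positive response are flagged,
not scaled.

Discernibility uses a subject-level percentile bootstrap (default 10,000
replicates, configurable down to 2,000 for speed): SE ≈ half-width of the
central 68% interval; a level is discernible when the 5th percentile of
the bootstrap distribution of the mean is positive (lower bound of the 90%
CI; one-tailed α = 0.05). Thresholds are grid-resolution-limited: lowest
discernible contrast (zero-contrast blank controls are never candidates)
and highest discernible frequency, with no psychometric-function
interpolation. Non-monotone significance patterns are logged, never
silenced.

**Calibration.** The percentile rule is an asymptotic α = 0.05 test; at
n = 6 subjects it is intrinsically anticonservative (one-tailed level
≈ 0.10, a property of the percentile bootstrap at tiny n, asserted as such
in the unit tests). The null-calibration check therefore runs at n = 40
subjects, where the level is ≈ 0.059 and within 0.05 ± 0.02. Because each
null level in a 6-fly tuning curve carries that ~10% false-flag rate,
the end-to-end recovery cohorts were designed a priori so that threshold
extraction is not hostage to it: the generator contrast threshold sits at
the lowest nonzero grid level (with a zero-contrast control present) and
the spatial/temporal cutoffs at the top grid level; recovery then measures
end-to-end detection power through the full chain. Sub-threshold
discrimination is characterised separately as a calibration-rate check.

**Synthetic traces.** Steering amplitude = per-fly gain (log-normal, 10%
spread) × a logistic in log₂-contrast (slope 6 per octave, centred half an
octave below threshold, so response at threshold is ~95% of saturation and
two octaves below is negligible) × a spatial low-pass (flat to the cutoff,
Gaussian roll-off above) × a temporal band-pass (tf/(tf+1) rise, sharp
roll-off above the cutoff), rising after motion onset with a 0.15 s time
constant, signed by motion direction. Added on top: per-fly directional
bias (SD 0.3 ΔWBA units), a baseline random walk (0.05 units over a trace)
and white noise (0.3 units/sample). The generator does not model
saccades, habituation across trials, or closed-loop dynamics; recovery
results certify the analysis chain, not biological response models.

## Morphometrics

Generalised Procrustes: translate to zero centroid, scale to unit centroid
size, rotate to the running consensus by SVD — with improper rotations
(reflections) allowed per shape, since facets from left and right eyes are
mirror forms — iterating until the consensus moves < 1e-8 (the consensus
orientation gauge is pinned to the first shape). PCA is the SVD of the
centred flattened coordinates (12 per shape); variance fractions sum to 1.
Clustering is Ward linkage on all PC scores; automatic cluster count picks
the cut maximising the relative within-inertia drop (the largest inertia
gain relative to the next gain), declining to split identical shapes.
Composition tests are Pearson chi-square without continuity correction
(df = (r−1)(c−1)); a zero expected count is an error and expected counts
below 5 warn. Landmark templates must be 6 ordered planar points; corner
correspondence (clockwise from the dorsal-most vertex) is a
data-preparation contract, since superimposition requires it.

## Problem sizes and tolerances

The validation suites run at desk scale as the package's own choice of
study conditions: one full-scale eye (600 lenses, ~500×490×150 voxels at
1 µm) for detection recovery; 100-seed coverage sweeps for slope CIs;
200-seed bias and 2,000-rep null sweeps for allometry; 100 six-fly cohorts
at 2,000 bootstrap replicates (plus a 4,000-sim null calibration at
n = 40) for psychophysics; 30-facet landmark sets for morphometrics.
Numerical tolerances follow the construction: exact identities are
asserted to machine precision, voxelisation-limited quantities to the
voxel scale, and Monte-Carlo rates to bands that include their binomial
error.

## Known limitations

* Detection is validated on ideal binary phantoms; real scans add
  segmentation noise upstream of this pipeline (manual cleaning is out of
  scope here, as it was in the source workflow).
* The biquadratic surface fallback supports flat/saddle lens sheets, but
  polar eye maps require the spherical model; strongly aspheric eyes would
  need a generalised chart centre definition.
* Auto equator alignment assumes the band of smaller facets is present and
  roughly great-circle shaped; heavily damaged eyes need manual rotation.
* Thresholds are grid-limited by design; between-level acuity requires a
  psychometric fit, which is deliberately not implemented.
* The bootstrap discernibility rule inherits its small-n anticonservatism
  from the procedure it implements; interpret 6-subject significance flags
  accordingly.
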