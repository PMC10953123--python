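# compoundeye

Analysis pipeline linking compound-eye morphology to predicted and measured
vision in *Drosophila*-scale flies. It covers the full chain used to compare
two sibling species (a *D. mauritiana* RED3-like morph with larger facets
and a *D. simulans* M3-like morph with more, smaller facets):

1. **ODA-3D detection** — find individual corneal lenses in a cleaned binary
   micro-CT volume and measure each lens's volume, diameter, cross-sectional
   area, length, optical axis and mean interommatidial (IO) angle Δɸ.
2. **Eye maps** — place lenses in eye-centred polar coordinates (elevation,
   azimuth), build 20-bin profiles with 3×SEM error bars, compute equatorial
   band statistics (elevation = 0 ± 15°), and compare per-subject azimuthal
   OLS slopes between species with a pooled-variance t-test.
3. **Allometry** — regress each optical summary metric on eye surface area
   SA = Σ π(d/2)² plus a dummy-coded species variable (the species contrast
   is the dummy's Wald t-test), mirroring the standard scaling-table layout.
4. **Optical limits** — the hexagonal-lattice Nyquist relation
   *f*ₛ = 1/(√3·Δɸ) and its inverse Δɸ = 1/(√3·*f*ₛ), plus contrast
   sensitivity as the reciprocal of the lowest discernible contrast.
5. **Psychophysics** — turn tethered-flight ΔWBA traces into tuning curves:
   fold left/right motion responses, baseline-correct (0.1 s pre-onset),
   average 0.5–1.25 s post-onset, normalise per fly, bootstrap 10,000× at
   the subject level (68% CI ≈ SE; significance when the 90% CI lower bound
   is positive), and read thresholds off the grid.
6. **Morphometrics** — six-corner facet landmarks, generalised Procrustes
   superimposition with reflection, PCA, Ward clustering with automatic
   cluster count, and chi-square composition tests.

Raw synchrotron scans and flight-arena recordings of the original study are
not publicly deposited, so a first-class synthetic-data module generates
ground-truthed stand-ins: voxelised lens lattices on spherical caps (with
facet-size gradients, an equatorial band of smaller facets and controllable
IO-angle profiles), 1000 Hz ΔWBA traces with per-fly gain, directional bias,
drift and noise, and landmark sets drawn from labelled shape templates.
Every stage is validated by parameter recovery against that ground truth.

## Worked example

Detect ommatidia in a synthetic eye and score the result against the
generator's ground truth:

```python
from compoundeye import synthetic, oda3d, eye_maps, optics

spec = synthetic.SyntheticEyeSpec(seed=20)      # 600 lenses, 290 µm radius
volume, truth = synthetic.generate_synthetic_eye(spec)
record = oda3d.detect_eye(volume)
record = eye_maps.to_polar(record)

print(record.lens_count)                        # 598  (600 true lenses)
print(round(record.lenses.io_mean_deg.median(), 2))   # 4.01 degrees
print(round(optics.nyquist_from_io(4.01), 3))   # 0.144 cycles/degree
```

The detector recovers 598 of 600 lenses (−0.3%), a mean centroid error of
0.03 µm, a mean diameter error of 0.41 µm and a median IO-angle error of
0.25°(`analysis/02_detect_ommatidia.py` prints the full report). The median
IO angle of ~4° corresponds to a hexagonal-lattice Nyquist acuity of
~0.14 cycles/degree — sharper than the behaviourally measured acuities
(0.1 / 0.08 cpd), as expected when optics are not the only limit.

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/`:

```bash
python analysis/01_simulate_eye.py      # ground-truthed synthetic eye
python analysis/02_detect_ommatidia.py  # ODA-3D detection + scoring
python analysis/03_eye_maps.py          # profiles, band medians, slopes
python analysis/04_allometry.py         # scaling models vs eye area
python analysis/05_optical_limits.py    # Nyquist / sensitivity tables
python analysis/06_psychophysics.py     # tuning curves and thresholds
python analysis/07_facet_shapes.py      # Procrustes + PCA + clustering
```

For instance `03_eye_maps.py` ends with the species contrast of azimuthal
lens-volume slopes, `t(10) = 2.60, d = 1.50, p = 0.027` on the default
cohort, and `06_psychophysics.py` prints per-species thresholds
(contrast sensitivity 7.1 vs 3.7, spatial acuity 0.08 vs 0.10 cpd,
temporal acuity 20 vs 50 Hz for the RED3-like vs M3-like cohorts).

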