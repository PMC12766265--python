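# Methods

## Coordinate and unit conventions

Axes: `x` along columns (rightward), `y` toward the image's "12 o'clock"
(row 0), `z` from the sample toward the sensor. Array element
`values[i, j]` sits at `x = j·px`, `y = (n_rows − 1 − i)·px`. Declination
is clockwise from +y viewed from the sensor side; inclination is positive
toward −z (into the sample), so (dec 0, inc 0) is the in-plane
magnetizing-field direction and the conventions agree with paleomagnetic
plotting. Rigid-transform rotations are clockwise-positive in the same
view (+90° maps (1, 0) → (0, −1)).

Interfaces use µm for lengths, A·m² for moments and tesla for fields;
field evaluators convert to SI metres internally. This keeps the ten
orders of magnitude between pixel noise (10⁻⁸ T) and moments (10⁻¹⁷ A·m²)
out of user-facing code.

## Forward model

A source is a point dipole at standoff `h > 0` below the sensing plane;
the field at a pixel center is the textbook expression
`B = (µ0/4π)[3r̂(m·r̂) − m]/|r|³` with `r` running from source to pixel.
Fields are evaluated at pixel centers only — no sub-pixel area
integration and no averaging over the NV layer thickness. The finite
sensing-layer thickness is absorbed entirely into the single 1 µm depth
correction (below). Multipole sources and magnetostatic interactions
between particles are out of scope.

Magnetite sizing assumes a single, spherical, non-interacting,
saturation-magnetized particle: `d = (6m/(π·Ms))^(1/3)` with
Ms = 480 kA/m. Moments of clusters therefore map to an *equivalent*
single-sphere diameter; the report flags diameters above 300 nm (default)
as probable clusters.

## Spectral transforms

In the source-free half-space above the sample all field components share
one harmonic potential, giving `B̂u(k) = T(k)·B̂z(k)` with
`T(k) = u_z − i(u_x k_x + u_y k_y)/|k|` under the package's FFT and axis
conventions. `axis_to_bz` divides by `T`; wavevectors with
`|T| < regularization_eps` (default 10⁻³) are zeroed, and a warning is
issued when the measurement axis is (nearly) in-plane, where part of the
spectrum is unrecoverable in principle. The sign of the imaginary part is
convention-dependent; it was fixed against the analytic dipole model and
is locked by a regression test.

At `k = 0` the transfer function is exactly `u_z`, so the DC level is
divided by `u_z` whenever that is resolvable (≥ regularization_eps) and
zeroed otherwise. This makes the `u = ẑ` case an exact identity instead
of introducing a spurious mean shift.

Padding and apodization: maps are zero-padded by `pad_factor` (default 2)
per axis; with the default `hann` apodization the data edges are
replicated into the padding band and rolled off with a half-Hann window.
The data region itself is never windowed — a full-frame Hann would
distort interior amplitudes, which the dipole fits consume. Upward
continuation multiplies the spectrum by `exp(−|k|·dz)`; downward
continuation is refused (noise amplification without bound). The raw
instrument's own processing chain presumably makes equivalent choices,
but they are not published; these defaults are declared, not inferred.

## Synthetic phantoms

`make_phantom` emulates the duplicate-acquisition design: acquisition 1
defines the sample frame; acquisition 2 is related by a rigid motion with
rotation uniform in ±3° and translation of nominal magnitude 100 µm
(±20%, random bearing) about the FOV center — the re-installation shift
of the real protocol. Sample sources keep their sample-frame positions
(and their in-plane moment components rotate with the sample); artifacts
keep their sensor-frame positions; contaminants are assigned to exactly
one acquisition. Truth bookkeeping records role, host (tissue/blank by
mask lookup), both sensor-frame positions, standoff and moment for every
source.

Default conditions: source depths uniform in 1.5–6 µm (standoff = depth
plus the 1 µm layer correction), artifact standoffs 0.2–1 µm (inside the
sensor), contaminant standoffs within the first micron, moments
log-uniform in 10⁻¹⁷–10⁻¹⁴ A·m², moment directions Fisher-distributed
(κ = 30) about the applied field for sample sources and uniform on the
sphere for artifacts and contaminants, i.i.d. Gaussian pixel noise of
50 nT, eight fiducial marks with 0.3 µm localization jitter, and a
connected tissue mask covering half the FOV. The 50 nT noise default is a
declared choice (no per-pixel figure is published for 12-hour
high-sensitivity maps) that puts a 3×10⁻¹⁷ A·m² source at ~2 µm standoff
near the detection margin. Phantoms default to a reduced 480 × 300 px
grid for speed; the full 1920 × 1200 px grid is one config field away.

Positions are rejection-sampled so that each source stays 30 µm (default)
from map edges in every acquisition containing it and at least
`exclusion_radius` (default 15 µm) from other sources per frame; a
phantom too crowded to place after 1000 attempts raises. The tissue mask
is a star-convex blob: a random interior center, a smooth random radial
profile (three Fourier harmonics), and a global scale bisected until the
covered fraction matches the request within 1%.

What the phantom does *not* model: ODMR-level physics (shot noise,
bias-field reversal residuals, global fluorescence), spatially correlated
strain backgrounds (strain is represented only as localized dipole-like
artifacts), optical blurring, and extended or interacting sources.
Passing tests therefore demonstrate correctness of the analysis chain
under its own assumptions, not robustness to every instrument systematic.

## Registration

The rigid transform between acquisitions is estimated from matched
fiducial pairs by the closed-form 2-D cross-covariance (Procrustes/Kabsch)
solution with the reflection branch rejected; the rotation pivot is fixed
at the FOV center and the per-point residual RMS is reported. Source
matching downstream always operates on fitted source *coordinates* pushed
through the point transform; map resampling (bilinear, missing pixels →
NaN) exists for visualization and difference imaging only, keeping
interpolation bias out of source positions. An automatic greedy
nearest-neighbor fiducial matcher (after coarse centroid alignment) is
provided as a best-effort convenience; curated correspondences by shared
id are the primary path, mirroring the visual identification of
neuromelanin-bearing cells in reflected-light images.

## Detection and inversion

Candidates are local extrema of |Bz| above `k_mad` (default 5) times the
robust noise scale 1.4826·MAD, merged within `min_sep` (default 10 px)
and wrapped in a 41 × 41 px window clipped at borders. The original
analysis selected signals visually; an explicit MAD rule replaces that
for reproducibility, with all thresholds exposed in config.

Each window is inverted by trust-region-reflective least squares
(`scipy.optimize.least_squares`, xtol/ftol/gtol 10⁻¹², distance bounded
below by 0.05 µm, ≤500 iterations' worth of evaluations) over the six
parameters (x, y, h, mx, my, mz). Initialization: (x, y) at the candidate
peak, h = 2 µm, |m| from the on-axis closed form `m = 2π h³ B_peak/µ0`.
Four starts differing in moment direction — applied field, its reverse,
+z, −z — guard against the local minima of tilted-dipole inversions; the
best residual wins. Non-convergence is flagged, never silently dropped.
Reported depth is `h − nv_layer_correction` with the correction fixed at
1.0 µm (the study's stated subtraction, not the 1–2 µm layer-thickness
range). No uncertainty quantification is attached to fit parameters.

## Provenance classification

`match_sources` pairs fits across acquisitions by mutual nearest
neighbor, first in the sample frame (acquisition-2 positions pushed
through the transform; acceptance within `tol`, default 5 µm — the
positional tolerance for "same location" is not published), then, among
the leftovers, in the raw sensor frame within `sensor_tol` (artifact
hypotheses — this second pass is what makes sensor-frame colocation
decidable at all). Remaining fits become singletons. Acquisition-2
moments are rotated into acquisition-1 axes; a sensor-frame pair reports
its shared sensor position as its coordinate.

Label priority is deterministic: **artifact** (sensor-frame colocated) >
**contamination** (singleton, or mean depth ≤ 1 µm) > **bona_fide**
(sample-frame colocated, mean depth > 1 µm, mean direction within the
direction rule of the applied field, and the two depth estimates within
2 µm of each other). Everything else — including pairs failing only the
direction rule — is **ambiguous**, as is every paired record when the
inter-acquisition translation is below 3× the matching tolerance (sensor
and sample frames then indistinguishable). The direction rule defaults to
hemisphere membership (< 90°), configurable to a tighter cone; the
source description ("aligned toward" the field) gives no numeric cone.
Depths combine as the mean of the two fits, since no combination rule is
published. Sources recurring across repeat map pairs of one FOV are
merged by positional clustering at the same tolerance
(`deduplicate_records`). Scratch-correlated contamination is handled by
an optional exclusion mask, not automated scratch detection.

## Statistics

Fisher statistics over unit directions: mean from the vector resultant,
κ = (n−1)/(n−R), α95 = arccos(1 − ((n−R)/R)((1/0.05)^(1/(n−1)) − 1)).
The 95% confidence region is the circular Fisher cone; the original
figures draw "confidence ellipses" (a feature of their plotting
software), but Fisher statistics as cited yields a cone and no ellipse
parameters are published, so containment tests use the cone. The tissue
preference test is the exact right-tailed binomial P(X ≥ k) with
p₀ = tissue area / FOV area (`scipy.stats.binomtest`; an exhaustive
enumeration oracle cross-checks it in the tests).

The TEM worked example converts a bulk specific moment (default
10⁻⁶ A·m²/kg, the literature maximum) into a number density of identical
d-nm spheres and an expected count per imaged volume. The section
thickness (100 nm) and tissue density (1000 kg/m³) are not stated by the
source of the printed value; they are explicit, defaulted parameters so
the assumptions stay auditable.

## Problem sizes used in the test suite

The suites run on reduced grids chosen to exercise every code path at
desk scale: single-source maps of 120 × 120 px for fit-recovery
statistics (100 noisy repeats), 256 × 256 px for spectral oracles,
960 × 600 px phantoms with 25 sources for the 20-seed classification
sweep (moments 2×10⁻¹⁵–10⁻¹⁴ A·m² so that the deepest sources still sit
at ≥10× the 50 nT noise, with a 30 µm exclusion radius so fit windows do
not overlap), and 240 × 200 px phantoms for pipeline determinism. The
full-size grid is exercised only through the geometry computations.

## Known limitations

* Overlapping dipoles are fit one window at a time; no joint multi-dipole
  inversion.
* The detection rule is isotropic in |Bz| and will merge lobes of very
  shallow in-plane dipoles closer than `min_sep`.
* `axis_to_bz` assumes a source-free sensing half-space and a uniform
  measurement axis across the FOV.
* The diamond's actual ⟨111⟩ axis orientation relative to the image axes
  is instrument-specific; `measurement_axis` is a free configuration
  parameter.
* Classification accuracy degrades gracefully but monotonically with
  noise; no attempt is made to recover sources below the MAD threshold.
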