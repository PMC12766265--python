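# qdmsource

Detection, inversion and provenance classification of magnetic dipole
sources in wide-field quantum-diamond-microscope (QDM) field maps — built
for the problem of finding individual magnetite nanoparticles in brain
tissue.

A QDM images the magnetic field over millimetre-scale fields of view
(1920 × 1200 px at 1.17 µm, i.e. 2.25 × 1.40 mm²) with enough sensitivity
to resolve the dipolar signal of a single ~50 nm magnetite crystal. The
hard part is not seeing dipoles but deciding *which* dipoles are real:
strain features in the diamond sensor and stray surface particles mimic
in-sample sources. The discriminating trick is to image every field of view
twice, removing, cleaning and reinstalling sample and sensor in between, so
the two acquisitions differ by a rigid motion of order 100 µm. Then

* **bona fide** in-sample sources occupy the same *sample-frame* position
  in both maps, sit deeper than 1 µm below the sensor, and are magnetized
  consistently with the in-plane field applied to the sample beforehand;
* **diamond artifacts** keep the same *sensor-frame* position (they travel
  with the diamond);
* **contamination** appears in only one of the two maps.

## What the package computes

* **Forward model** — point-dipole field `B(r) = (µ0/4π)[3r̂(m·r̂) − m]/|r|³`
  sampled at pixel centers, either the out-of-plane component `Bz` or the
  projection onto a single NV ⟨111⟩ axis (`qdmsource.physics`).
* **Spectral transforms** — recovery of `Bz` from a raw single-axis map via
  the per-wavevector division `B̂z = B̂u / T(k)`,
  `T(k) = u_z − i(u_x k_x + u_y k_y)/|k|`, and upward continuation
  `exp(−|k| dz)` (`qdmsource.spectral`).
* **Rigid registration** — closed-form 2-D Procrustes fit of the
  rotation + translation between duplicate acquisitions from matched
  fiducial landmarks (`qdmsource.registration`).
* **Inversion** — six-parameter least squares `(x, y, h, mx, my, mz)` per
  detected candidate, with depth = fitted map-to-source distance − 1 µm of
  NV-layer correction (`qdmsource.detect`).
* **Provenance classification** — mutual-nearest-neighbor matching across
  acquisitions in both frames, then the label rules above
  (`qdmsource.classify`).
* **Statistics** — Fisher mean direction with κ = (n−1)/(n−R) and the 95%
  cone α95, exact one-tailed binomial tests for tissue preference,
  magnetite sphere sizing d = (6m/πMs)^(1/3) at Ms = 480 kA/m, and a
  noise-floor survey of the smallest fitted moments (`qdmsource.stats`).
* **Synthetic phantoms** — duplicate-acquisition pairs with ground truth
  for every source, the test bed for the whole chain
  (`qdmsource.phantom`).

## Worked example

Run the full chain on a synthetic acquisition pair (5 in-sample sources,
5 diamond artifacts, 3 contaminants, 50 nT pixel noise, ~100 µm shift):

```python
from qdmsource import PhantomConfig, RunConfig, run_pipeline, score_against_truth

cfg = RunConfig(seed=7)
cfg.phantom = PhantomConfig(
    n_sample_sources=5, n_artifacts=5, n_contaminants=3,
    moment_range=(2e-15, 1e-14), n_cols=480, n_rows=300, seed=7,
)
res = run_pipeline(cfg)            # optionally: run_pipeline(cfg, outdir="run7")
print(res.stats["label_counts"])
print(res.stats["fisher"])
print(score_against_truth(res.records, res.pair)["confusion"])
```

prints

```
{'artifact': 5, 'bona_fide': 5, 'contamination': 3}
{'n': 5, 'mean_dec': 3.34, 'mean_inc': 5.36, 'resultant_R': 4.87,
 'kappa': 30.8, 'alpha95_deg': 13.99, 'contains_applied_field': True}
{'artifact->artifact': 5, 'bona_fide->bona_fide': 5, 'contamination->contamination': 3}
```

Every planted source is recovered with its correct provenance. The five
bona fide sources have a Fisher mean direction (dec 3.3°, inc 5.4°) whose
95% confidence cone (α95 ≈ 14°) contains the applied-field direction
(dec 0°, inc 0°) — exactly the consistency check used to accept in-sample
sources. The estimated inter-acquisition transform (rotation 0.79°,
translation (−114.3, 18.7) µm, fiducial residual 0.56 µm) matches the
phantom's true rigid motion.

The same chain is exposed on the command line:

```sh
qdmsource pipeline --seed 7 --out run7        # all stages on a phantom
qdmsource simulate --seed 3 --out sim3        # phantom + ground truth only
qdmsource detect sim3/map1.tif --out fits1.csv
```

## Layout

```
src/qdmsource/    physics, spectral, phantom, registration,
                  detect, classify, stats, io, pipeline, report, cli
tests/            unit + property + acceptance suites
docs/methods.md   models, conventions, parameter choices, limitations
scripts/          acceptance.py
```
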