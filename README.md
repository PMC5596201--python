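# radpathcorr

A self-contained pipeline for correlating ex vivo MRI with digital
histopathology on small surgical specimens, exercised end to end on a
synthetic specimen phantom.

The scientific question the pipeline addresses: does the mean diffusivity
(MD) measured by diffusion tensor imaging of a fixed specimen predict the
cellularity measured by counting nuclei on the histology sections cut from
the same specimen? Because water diffuses less freely in densely packed
tissue, MD is expected to correlate *negatively* with cell density. Testing
this requires a chain of steps, each of which this package implements:

1. **Synthetic specimen generator** (`radpathcorr.phantom`) — a specimen
   embedded in agarose gel with fiducial markers, imaged as T1-, T2- and
   T2\*-weighted volumes and a 7-frame DWI series (Rician noise), then
   "sectioned" into digital histology images whose per-tile nucleus counts
   are generated from the ground-truth MD through a linear coupling with
   Poisson sampling. Ground-truth tensors, labels and the exact
   MR-to-histology affine (shrinkage 0.8) are exposed for validation.
2. **Diffusion tensor fitting** (`radpathcorr.dti`) — rigid intra-series
   alignment of the DWI frames, noise estimation from background air,
   weighted linear least squares tensor fit, positive-definiteness
   enforcement by a constrained refit, and MD maps.
3. **Registration** (`radpathcorr.registration`) — intensity-based affine
   alignment of the weighted contrasts to the T2w reference, and a
   closed-form landmark affine from the MD map to histology pixels using
   the specimen pieces and markers as fiducials.
4. **ROI statistics** (`radpathcorr.roistats`) — ROI means/SDs, control
   normalisation against a gel ROI, and unpaired two-tailed t-tests over a
   fixed design of 45 region/contrast comparisons.
5. **Cellularity mapping** (`radpathcorr.cellularity`) — nucleus detection
   with watershed declumping, scaling of section counts to the full MR
   slice thickness, a colour-binned 100 µm tile map, and the
   MD-versus-cellularity Pearson correlation.

The model, the default parameters (which are the study conditions used by
every test and script), the numerical choices and the known limitations are
documented in [docs/methods.md](docs/methods.md).

## Worked example

The `radpath` CLI runs the full pipeline — simulate, fit, register,
tabulate, count, correlate — into one workspace directory:

```
$ radpath --seed 0 --out-dir out run-all
{
 "seed": 0,
 "n_comparisons": 45,
 "pearson_r": -0.6589231013789136,
 "n_pixels": 15,
 "recovered_singular_values": [
  32.04309018276582,
  31.98304296628704
 ],
 "true_shrinkage": 0.8
}
```

Reading the summary:

* `pearson_r = -0.659` over 15 matched MD-pixel/histology-ROI pairs: fitted
  MD correlates negatively with estimated cellularity, as expected. (The
  magnitude is attenuated below the generative coupling because the nucleus
  detector undercounts overlapping nuclei in the densest regions; see the
  limitations section of docs/methods.md.)
* The landmark affine's singular values are 32.043 and 31.983 histology
  pixels per MD pixel. One MD pixel is 200 µm and one histology pixel is
  5 µm, so the physically recovered shrinkage is 32.043 × 5/200 = 0.8011
  and 31.983 × 5/200 = 0.7996 — within 0.13% of the true factor 0.8.
* All 45 ROI comparisons (15 region pairs × 3 contrasts) are written to
  `out/stats/comparisons.csv`, e.g. the hyperintense rim versus the
  calcified core on T1w gives t = 244.9, p = 5.4 × 10⁻⁷⁶.

The run takes roughly 60–80 s on one CPU and is byte-identical across
repeated invocations at the same seed. Every stage is also available as its
own subcommand (`simulate`, `fit-dti`, `register-contrasts`,
`register-histology`, `roi-stats`, `cellularity`, `correlate`) operating on
the shared workspace, and as a Python function:

```python
from pathlib import Path
from radpathcorr import pipeline

summary = pipeline.run_all(Path("out"), seed=0)
print(summary["pearson_r"])   # -0.6589231013789136
```

Selected per-stage outputs for seed 0: the noise SD estimated from the
field-of-view corners of the b=0 image is 25.68 (true 25); all 7 DWI frames
register successfully; the four landmark residuals are 0.25–1.30 histology
pixels (1.3–6.5 µm).

## Package layout

```
src/radpathcorr/
  phantom.py       synthetic specimen generator and ground truth
  io.py            NIfTI/TIFF/CSV/JSON readers and writers
  dti.py           noise estimation, WLLS tensor fit, PD refit, MD maps
  registration.py  intensity affine/rigid + landmark affine + ROI transfer
  roistats.py      ROI statistics, normalisation, t-tests
  cellularity.py   nucleus detection, section scaling, tile maps, correlation
  pipeline.py      stage orchestration and the run-all driver
  cli.py           `radpath` command-line interface
docs/methods.md    models, parameters, numerical choices, limitations
scripts/acceptance.py  descriptive quantities as JSON
tests/             pytest suite (tests/test_acceptance.py holds the
                   acceptance tests)
```
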