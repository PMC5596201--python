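# Methods

This document records the models implemented in `radpathcorr`, the default
parameters, the scope of the synthetic data generator, the numerical choices
that matter for reproducing results, and the known limitations.

## 1. Synthetic specimen phantom

The generator (`radpathcorr.phantom`) stands in for a small formalin-fixed
surgical specimen embedded in 2% agarose gel inside a container, scanned
ex vivo and then processed to paraffin histology. It is the single source of
every input the pipeline consumes, and its defaults are the study conditions
used everywhere (tests, the acceptance script, the CLI `run-all`).

### Geometry

All compartments are analytic 2-D shapes extruded through 3 slices
(a thin-slab acquisition around the analysed slice):

| compartment | shape | role |
| --- | --- | --- |
| air | background | signal void outside the container |
| agarose | disk r = 7.8 mm | gel reference, control ROI host |
| tissueA_rim | annulus 1.4–2.6 mm | hyperintense tissue rim |
| tissueA_core | disk r = 1.4 mm | calcified, near-zero signal core |
| tissueB | rotated ellipse 2.4 × 1.9 mm | main tissue mass |
| tissueB_hemosiderin | two disks r = 0.5 mm | T2\*-dark inclusions |
| vessel | disk r = 0.5 mm | blood-vessel profile in the gel |
| marker1 | disk r = 1.2 mm | round pasta fiducial |
| marker2 | letter glyph, 2 mm | orientation fiducial |

Grids: weighted contrasts 160 × 160 × 3 at 0.1 × 0.1 × 0.3 mm; DWI
80 × 80 × 3 at 0.2 × 0.2 × 0.3 mm; field of view 16 × 16 mm. Digital
histology is rendered at 5 µm/pixel (3200 × 3200) for section levels
(1, 11, 25, 35).

### Signal models

* Weighted contrasts (T1w, T2w, T2\*w) are piecewise constant per
  compartment plus Gaussian noise (SD 15). The zero-noise limit is exactly
  piecewise constant.
* DWI: `S_i = S0 · s0_scale · exp(−b_i gᵢᵀ D gᵢ)` with per-compartment
  ground-truth tensors, `S0 = 1000`, `b = 1000 s/mm²`, one b=0 frame plus
  six tetrahedron-derived unit directions. Rician noise (σ = 25) is applied
  as the magnitude of a complex signal with Gaussian noise on both
  channels. `s0_scale` models proton density: 0 for air, 0.05 for the
  calcified core.
* Histology: a grayscale template per compartment with dark disks (radius
  5 µm) for nuclei. Per 100 × 100 µm tile, nucleus counts are Poisson with
  mean `max(c0 − c1·MD + ε, 0)` in tissue (defaults `c0 = 75` cells/tile,
  `c1 = 7·10⁴` cells·tile⁻¹·(mm²/s)⁻¹, ε Gaussian with SD 4), and fixed
  densities elsewhere (gel, markers, vessel lumen and the acellular core
  are 0). Placement noise is independent across levels; geometry is shared.

### MR-to-histology ground truth

Paraffin processing is modelled as a linear shrinkage factor 0.8 applied
about the image centre (no rotation by default). The generator exposes the
exact affine from MR millimetres (and from MD-map pixel indices) to
histology pixel indices. Pixel coordinates are array-index coordinates:
pixel *i* is centred at physical position `(i + 0.5) · pixel_size`.

### Determinism

Every random stream is derived as `default_rng([seed, stream])` with fixed
stream IDs (weighted noise 100+k, DWI 200, histology 300+level, pixel
selection 400). Volumes are written as uncompressed `.nii`; a `run-all` at a
fixed seed is byte-identical across runs.

## 2. Diffusion tensor estimation

Per voxel the log-linearised model `ln S_i = ln S0 − b_i gᵢᵀ D gᵢ` is solved
by weighted linear least squares with weights `w_i = (S_i/σ)²` — the
first-order variance correction appropriate for log-transformed magnitude
data — in a single pass using the observed signals. Scaling σ by a constant
rescales all weights equally and leaves the solution unchanged; the
fit is therefore invariant to the absolute noise scale and matches an
ordinary least-squares oracle on the pre-whitened system exactly.

Voxels with any non-positive signal are excluded (the log is undefined).
The map-level fit batches the weighted normal equations over all voxels.

**Noise estimation.** σ is estimated from the b=0 image over the
field-of-view corners, which lie in air outside the container: the
magnitude there is Rayleigh distributed, so σ = SD/√(2 − π/2). The fit
mask is `b0 > 4σ`.

**Positive definiteness.** Tensors with a negative eigenvalue are refit
with `D = LLᵀ` (modified Cholesky, 6 free parameters, ln S0 profiled out in
closed form), minimising the same weighted objective with L-BFGS-B and an
analytic gradient, initialised at the eigenvalue-clamped projection of the
unconstrained fit. The result always satisfies λ₃ ≥ −10⁻¹² and its weighted
residual never exceeds the clamped projection's (otherwise the voxel is
flagged and excluded). MD = trace(D)/3 = mean eigenvalue; excluded voxels
carry NaN. The ×1000 display convention is applied only when rendering.

## 3. Registration

**DWI frames → b=0 (rigid).** The similarity metric is negated normalised
cross-correlation, not mean squares: diffusion weighting attenuates each
compartment differently, so b-weighted frames differ from the b=0 reference
by per-structure intensity scaling, which a mean-squares criterion
mis-registers (empirically it drags geometry by multiple voxels) and an
intensity-invariant criterion handles. Optimisation is regular-step
gradient descent restricted to in-plane rotation and translation: with 3
structurally identical slices, through-plane motion is not identifiable (a
z-shift only smooths noise). If the optimised metric is no better than the
identity's, the frame is kept unregistered and flagged.

**T1w/T2\*w → T2w (affine).** Mattes mutual information (32 bins), since the
contrasts differ. Both registrations evaluate image gradients by central
differences rather than the recursive Gaussian filter, which requires ≥ 4
samples per axis and fails on 3-slice slabs. In-plane self-registration
accuracy is at the 0.05-pixel level; the through-plane affine scale is not
identifiable on a 3-slice slab and is not interpreted.

**MD map → histology (landmark affine).** Four fiducials (the two tissue
pieces and the two markers) are reduced to centroids; a 2-D affine is
solved in closed form by least squares. Source centroids are measured on
the fine 0.1 mm weighted-image grid — where fiducials are legible — and
converted to MD pixel coordinates through the shared physical frame; the
coarse 0.2 mm MD raster aliases the letter-glyph centroid by up to a pixel,
which alone would exceed a 1% scale error. With 3 non-collinear pairs the
solution is exact; with 4+ pairs per-landmark residual distances are
reported. Converting the pixel-index affine to physical units
(`(i + 0.5)·pixel_size` convention) makes the singular values the recovered
shrinkage: 0.8001 and 0.7996 against a true 0.8 on the default phantom
(≤ 0.13% error).

## 4. ROI statistics

ROIs are axis-aligned rectangles in physical micrometres; a voxel belongs
to an ROI when its centre falls in the half-open rectangle. Statistics are
the mean and sample SD (n−1); ROI means are additionally normalised to an
agarose control ROI per contrast. Pairwise comparisons use the unpaired
pooled-variance Student t-test, two-tailed, over a fixed design of 15 ROI
pairs × 3 contrasts = 45 comparisons, flagged at α = 0.05 without
multiple-testing correction (a Bonferroni flag is emitted as a
supplementary column). Degenerate zero-variance cases use recorded
conventions (equal means → p = 1; unequal → p = 0 with a warning) and are
flagged.

## 5. Cellularity mapping

The nucleus detector is a deliberately simple, documented stand-in for
proprietary slide-analysis software: global dark-object threshold at
`min + 0.5·range`, watershed segmentation seeded at distance-transform
peaks (so touching nuclei split rather than count as one clump), and a
20–2000 µm² area filter, one centroid per segment. Without the watershed
split, contiguous nuclei in dense regions merge and saturate counts — on
the phantom this inverts the sign of the MD–cellularity correlation, so the
declumping step is a correctness requirement, not a tuning choice. A manual
corrections record (add/remove by coordinate) replaces interactive editing.

Counts from the assessed section levels are averaged and multiplied by the
number of interval sections (default 35) to estimate cells per MR slice
thickness; `estimate = mean × n_intervals` holds exactly on every tile.
The tiled map uses sequential 100 µm tiles from the tissue-mask bounding
box; the 11 colour bins are white for exactly 0 then 250-cell-wide bins to
2500, interior boundaries belonging to the lower bin, values above 2500
clamped to the top bin with a warning.

## 6. MD–cellularity correlation

Fifteen MD pixels with variable MD are selected (one random pixel per MD
quantile band inside the tissue mask), mapped through the landmark affine,
and paired with estimated counts in 200 × 200 µm histology ROIs at the
matched positions; the Pearson coefficient is reported signed, with the
magnitude separately.

For correlation-recovery experiments the generative coupling is calibrated
per sample: with counts Poisson around `c0 − c1·MD + ε`, the law of total
variance gives the population correlation
`ρ = −c1·sd(MD) / sqrt(c1²·var(MD) + E[µ] + sd(ε)²)`, so the jitter SD that
achieves a target ρ is solved in closed form from the MD values actually
selected. The calibration raises an error when the target is unattainable
(Poisson noise alone caps |ρ|) or when the linear mean would clamp at zero
inside the MD range.

## 7. Limitations

* The hemosiderin inclusions are the densest tissue (≈ 33 cells/tile);
  even with watershed declumping the detector undercounts overlapping
  nuclei there, which attenuates the end-to-end correlation magnitude
  (seed 0: r = −0.66 at n = 15) relative to the calibrated sampling
  experiments.
* The calcified core is a signal void (`s0_scale = 0.05`), falls below the
  4σ fit mask and is excluded from fitted MD; end-to-end correlations
  therefore never see the lowest-MD compartment.
* Through-plane parameters (rigid z-shift, affine z-scale) are not
  identifiable on 3-slice slabs; they are constrained out (rigid) or left
  uninterpreted (affine).
* The nucleus detector is not a model of any specific commercial tool; its
  absolute counts matter only through the coupling model of the generator.
* Red blood cells (anuclear, capable of depressing MD without raising
  nucleus counts) are not modelled.
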