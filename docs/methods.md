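# Methods

`fsesim` simulates clinical T2-weighted single-shot fast-spin-echo (FSE)
acquisitions — HASTE-style (Siemens naming) and SS-FSE-style (GE naming) —
of the fetal brain from a segmented 3D anatomical model. This note documents
the model, its assumptions, the tunable parameters, the numerical choices,
and what the bundled synthetic data do and do not establish.

## Pipeline

1. **Anatomy** (`anatomy`). A 3D integer label volume (NIfTI) is merged into
   three tissue classes — gray matter, white matter, cerebrospinal fluid —
   via a user-editable legend. Each class receives scalar T1/T2 (ms) at the
   simulated field strength; background voxels carry T1 = T2 = 0 and produce
   no signal. Going from 1.5 T to 3 T multiplies T1 by 1.25 (GM) and 1.10
   (WM, CSF) and leaves T2 unchanged.
2. **Bias field** (`inu`). Transmit-field (B1+) inhomogeneity is a smooth
   multiplicative field, loaded or synthesized as a low-frequency Gaussian
   random field, normalized so that over the brain mask it spans [0.8, 1.2]
   (divide by mask-max/1.2, clip the lower tail at 0.8).
3. **Signal formation** (`epg`). Per voxel, the echo-train amplitudes are
   computed with the extended phase graph (EPG) formalism: 90° excitation
   about y, refocusing about x (CPMG condition), ideal unit crusher per half
   echo-spacing, relaxation operators per half period, echo amplitude
   |F+(0)|. The local bias-field value scales both excitation and refocusing
   flip angles. The result is the "T2 decay matrix": echo amplitude per
   voxel per echo.
4. **Motion** (`motion`). Inter-slice rigid excursions at three levels
   (uniform ±1/±3/±4 mm and ±2°/±5°/±8°), at most 5 % of slices corrupted,
   independent per corrupted slice and non-cumulative. Intra-slice motion
   and signal drops are not modeled.
5. **Acquisition** (`acquisition`). Per slice: Gaussian slice profile
   (FWHM = thickness, truncated at ±1.5·thickness, 0.1-mm integration
   steps), one k-space phase line per echo with the central (DC) line at the
   effective TE, GRAPPA-style neighbor copying of stride-skipped lines,
   Hermitian fill of the unsampled partial-Fourier region, optional Fermi
   filtering (radius 0.85, width 1/23 of the per-axis Nyquist radius) and
   zero-interpolation filling, complex Gaussian noise on every k-space
   sample, centered orthonormal 2D inverse FFT, magnitude, crop of the
   phase-oversampling margin. Slices are acquired interleaved (even indices
   then odd).
6. **Ground truth & metrics** (`anatomy.export_label_series`, `metrics`).
   Label stacks matched to each series by nearest-neighbour resampling under
   the same per-slice transforms (with an optional ventricle/CSF label
   merge); NRMSE (range-normalized), local SSIM (Gaussian window SD 1.5,
   dynamic range 255, K1 = 0.01, K2 = 0.03) and its mean (MSSIM); a motion
   index from inter-slice brain-mask centroid dispersion.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| HASTE: TE / ESP / ETL | 90 ms / 4.08 ms / 224 | effective echo index = round(TE/ESP) = 22 |
| HASTE: accel / ref lines / noise SD | 2 / 42 / 0.15 | GRAPPA-style copy approximation |
| HASTE: FOV / base / phase res / oversampling | 360 mm / 320 / 70 % / 80 % | phase grid 404 lines; 1.13 mm reported pixel |
| SS-FSE: TE / ESP / noise SD | 116.256 ms / 10 ms / 0.01 | ZIP to 512×512 with Fermi filter |
| Slice thickness / gap | 3 mm / 0.3 mm (HASTE), 0 (SS-FSE) | profile FWHM = thickness |
| Motion levels | ±1/±3/±4 mm, ±2/±5/±8° | ≤ 5 % corrupted slices (floor) |
| FOV shift | ±1.6 mm along slice-select | partially-overlapping repetitions |
| 1.5 T class T1/T2 | GM 2000/150, WM 3000/230, CSF 4000/1200 ms | literature-plausible defaults, overridable; quantitative tests supply their own |
| INU quantization | 0.01 | voxels sharing (T1, T2, flip scale) simulated once |
| Fine through-plane step | 0.1 mm | slice-profile integration |

## Numerical choices

- **EPG state ladder**: truncated at K = 2·ETL + 2 dephasing orders. With
  two unit crusher shifts per echo period the maximum reachable order is
  2·ETL, so this is exact for this pulse class; verified against a
  4096-spin isochromat Bloch ensemble to < 1e-3 (agreement is at machine
  precision in practice).
- **TR recovery is not simulated**: the sequences are single-shot and full
  longitudinal recovery between slices is assumed. A known limitation.
- **Effective echo index**: the printed HASTE TE (90 ms) is not an integer
  multiple of the echo spacing (4.08 ms); the central line is assigned to
  the nearest echo, round(TE/ESP).
- **Line ordering**: a linear sweep whose start is chosen so that exactly
  m−1 acquired lines precede the DC line (m = effective echo index). The
  realized partial-Fourier fraction therefore follows from the TE rather
  than being prescribed; lines below the sweep start are completed by
  Hermitian symmetry. The Nyquist row (index 0 of an even grid) is its own
  conjugate partner and stays zero when unsampled.
- **GRAPPA approximation**: skipped lines copy their nearest acquired
  neighbor, ties broken toward DC. No coil model is used.
- **Noise scale**: the noise SD applies to k-space values produced by an
  orthonormal (unitary) FFT of the object in units of the initial
  magnetization (EPG amplitudes ≤ 1), making 0.15/0.01 dimensionless and
  matrix-size-comparable. Noise is added after windowing/zero-filling so it
  fills the full reconstruction grid (interpretive choice).
- **Projection fast path**: for axis-aligned (identity-transform) slices the
  Gaussian-profile integration composed with trilinear interpolation
  factorizes exactly into per-voxel-plane hat weights followed by one 2D
  bilinear resample per tissue/flip combo; moving slices batch all fine
  offsets into a single interpolation per combo. Both paths are equivalent
  to the naive fine-grid evaluation up to floating-point ordering.
- **Motion index**: two-point population variances of adjacent-slice
  centroid coordinates over the central third of usable slices, summed and
  divided by the number of slices considered. The index is quoted in mm
  (following common usage) although a variance carries mm²; boundaries 0.5
  and 1.0 classify as moderate.
- **SSIM normalization**: both images are mapped by the affine transform
  sending the *reference* min/max to [0, 255]; a constant reference is
  shifted only. This keeps MSSIM continuous for near-identical images.
  Volumetric SSIM is used when all three dimensions hold the 11-sample
  window; thinner stacks are scored slice-wise along the thinnest axis.
- **Degenerate inputs**: constant bias fields normalize to a unit field with
  a warning; empty masks, non-integer label volumes, 4-D inputs, unmapped
  labels, and out-of-train echoes raise contract errors.

## Synthetic phantom: what it is and is not

The bundled generator produces deterministic brain-like geometry:
concentric smoothed ellipsoids (outer CSF shell, cortical gray ribbon,
white-matter core) perturbed by a low-frequency radial deformation, plus
ventricles (exact ellipsoids), deep-gray nuclei, corpus callosum and
cerebellum, labeled from the standard structure vocabulary so that all three
tissue classes and their adjacencies are exercised. It emulates the *scale*,
*topology* and *class composition* of a segmented fetal-brain atlas — not
real cortical folding, gestational-age-dependent anatomy, white-matter
lamination, or per-structure relaxometry. A green test on the phantom
establishes the correctness of signal formation, sampling, motion and
bookkeeping; it does not establish anatomical realism of the images.

## Known limitations

- No B0 off-resonance, diffusion weighting of EPG states, eddy currents,
  gradient-timing modeling, coil sensitivities, or maternal anatomy.
- No intra-slice motion or signal-drop artefacts.
- Scalar per-class relaxation times: no maturation-dependent or
  intra-structure T1/T2 variation.
- GRAPPA is a zeroth-order copy, not a kernel-based reconstruction.
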