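# Methods

## Overview

`centrioscope` quantifies centriole number and 3D length in multi-channel
immunofluorescence z-stacks of mitotic cells, together with the population
statistics used to compare cell lines (percentage of amplified cells,
percentage of cells with overly long centrioles, mean length,
variance-to-mean ratio, and an independence test between the two defects)
and pole-wise PCM / microtubule intensity asymmetry. It ships a synthetic
stack generator with full ground truth, so the entire pipeline is testable
with no external image data.

## Mitotic-figure detection

A mitotic figure combines condensed chromatin (bright DNA staining) with a
bright spindle (tubulin). The detector works on 2D maximum-intensity
projections of the two channels:

1. Project both channels along z (MaxB for DNA, MaxR for tubulin).
2. Smooth each projection with a Gaussian of σ = 1.15 µm.
3. Multiply element-wise into a correlation image CM, which is bright only
   where both signals coincide.
4. Threshold CM with Otsu's method (256-bin histogram; object = strictly
   above threshold).
5. Compute S/N = (mean CM over the Otsu object class) / (mean over the
   rest). If S/N > 2.5 keep the Otsu mask; otherwise replace it with the
   robust mask CM > mean + 6·sd. The branch decision is global per field:
   one S/N value decides the thresholding mode, because S and N are grand
   means of the two classes and a per-object ratio is ill-defined when the
   mask is empty.
6. Dilate with a 2.2 µm disk, drop objects with convex-hull circularity
   Circ = (H−O)/H ≥ 0.2 ("edgy" objects), drop objects smaller than
   400 µm², and dilate survivors by 2.2 µm again so each region also
   covers centrioles near the spindle.

Connected components use 8-connectivity; regions touching the field border
are kept and flagged. All thresholds are exposed in `MitoticParams`
(sigma_um 1.15, snr_min 2.5, k_sd 6, dilate_um 2.2, circ_max 0.2,
min_area_um2 400).

A structural note on the robust branch: for a two-level image with object
fraction f, the field sd is at least √(f(1−f)) times the object elevation,
so mean + 6·sd exceeds the object level whenever f ≳ 3%. A robust-branch
mask therefore can never be a large solid object; in practice (and in the
dim synthetic preset) it consists of texture peaks of the mitotic figure,
which the 2.2 µm dilation fuses into one region that passes the area gate.

## Centriole detection and measurement

Within each region, the centrin (and, in dual-marker mode, CP110)
projection restricted to the region is upsampled ×8 with bicubic
interpolation and thresholded with Otsu's method. The Otsu histogram is
restricted to in-region pixels: the zero padding outside the region mask
is an artefact of the ROI frame and would otherwise dominate the
histogram. Candidates are filtered by area at original scale
(0.1 ≤ A ≤ 1.0 µm²) and, in dual-marker mode, by colocalisation: a
candidate is kept only when its Manders overlap coefficient
R = Σab/√(Σa²·Σb²) with the CP110 image over its own pixels is ≥ 0.5 *and*
the CP110 Otsu mask intersects it. This is the step that removes
centriolar satellites (centrin-positive granules lacking the second
marker), the main source of single-marker false positives.

Each candidate is grown into 3D: every z-plane of the centrin channel in
the candidate's bounding box is bicubically upsampled ×8 in-plane (z is
never upsampled), voxels above the candidate's stored Otsu threshold
within the candidate footprint (dilated by one upsampled pixel) are kept,
and 26-connected components substantially overlapping the footprint are
extracted. A single 2D candidate may cover several structures that are
distinct in z; all overlapping components are kept, and components reached
from several candidates are merged into one complex so that nothing is
counted twice.

Each complex is then recursively split:

- **Principal frame.** Unweighted PCA of the voxel cloud after scaling
  indices to nanometres (x, y by pixel size / 8; z by the plane spacing),
  so the axial anisotropy of the acquisition is honoured. Because the
  point-spread function is ~3× wider axially (σz ≈ 300 nm vs
  σxy ≈ 100 nm), a thresholded in-plane rod is smeared over ~1 µm of z
  and raw PCA would call z the long axis of every sub-µm centriole. The
  PSF's covariance is axis-aligned and additive, so the pipeline subtracts
  diag(σz², σxy², σxy²) from the cloud covariance before the
  eigendecomposition (moment-based deblurring; σ values configurable in
  `CentrioleParams`, disabled by setting them to 0).
- **Axial profile.** Voxel intensities are binned along the first
  principal axis into a mass profile (per-bin sum). Bin width is one
  upsampled pixel, widened to the voxel lattice's projection on the axis
  so steep axes do not comb into empty bins; empty bins are bridged by
  linear interpolation and the profile is lightly smoothed ([1,2,1]/4).
  The Sobel derivative [-1,0,+1] flags steep flanks.
- **Cuts.** One cut per genuine intensity valley: an interior local
  minimum whose depth below both flanking maxima is ≥ 20% of the profile
  maximum and whose neighbourhood carries a Sobel response ≥ 25% of the
  maximum interior response. Cutting at the valley floor (rather than at
  each Sobel response flank) yields exactly two children for a dumbbell
  of touching rods. Cuts are kept ≥ 100 nm from the profile ends and
  ≥ 150 nm apart — no centriole is that short. Each voxel joins the
  segment below its cut plane (ties to the lower segment); segments are
  re-checked for 26-connectivity, and sub-30-voxel slivers that are
  26-adjacent to a larger sibling are rejoined to it. Splitting is exactly
  conservative: the terminal objects partition the grown voxel set.
- **Termination.** A branch ends when it yields no cut, its axial extent
  falls below 2 upsampled pixels, or recursion depth reaches 10.

**Length.** The default measurement is the distance between the
half-maximum crossings of the axial ridge profile (per-bin maximum
intensity, crossings linearly interpolated). For a structure blurred by a
Gaussian PSF the half-maximum point of an edge sits at the true edge, so
this estimate is unbiased, whereas the raw voxel extent includes the
threshold-dependent PSF spill (+2σ·Φ⁻¹(1−t/A) per end — typically +40% on
a 250 nm rod, +20% on 500 nm at the Otsu operating point). The voxel
extent plus a one-pixel end cap (`length_mode="extent"`, exact for ideal
binary rods and used by the geometric unit tests) and the eigenvalue
scaling 2·√(3·λ₁) (`"eigen_scaled"`, equal to the extent for a uniform
rod) remain available behind the config switch.

Per-cell results are `CellRecord`s: a cell is **amplified** iff it carries
more than 4 centrioles; a centriole is **overly long** iff it measures
strictly more than 500 nm (twice the normal centrin-measured length).

## Population statistics

- Line summaries: % amplified cells, % cells with ≥ 1 overly long
  centriole, pooled mean length and variance-to-mean ratio
  (sample variance, n−1, divided by the mean; an alternative per-cell-mean
  pooling and the n-denominator are available by flag).
- Cut-offs for calling a line defective come from control (non-cancerous)
  lines: mean + 2·sd of their per-line percentages, with mean and sd
  rounded to integer percent before combining (the precision at which
  screen percentages are reported). Controls averaging 7% ± 3 give the
  13% amplification cut-off; 1% ± 2 give the 5% over-elongation cut-off.
- Independence of amplification and over-elongation: Pearson chi-square
  (df 1, no continuity correction by default; Yates by flag) on the 2×2
  table of *centrioles* cross-classified by (cell amplified) ×
  (centriole > 500 nm), plus the observed and expected percentage of
  overly long centrioles per amplification stratum. A per-cell variant is
  provided but not default.
- Two-proportion comparisons use the pooled z statistic with the caller's
  choice of tail.

## PCM and microtubule asymmetry

Centrosome detection for intensity work uses Yen's threshold on the
maximum projection as a *minimum* threshold for 3D object detection
(26-connected voxels above threshold). Integrated density = sum of object
voxel intensities; the local background term is the mean of the
average-intensity z-projection over the object's xy footprint times the
voxel count (a whole-projection variant is available by flag), and the
corrected density is clamped at zero. This correction is exact on flat
backgrounds and assumes the object is thin relative to the stack.

Pole asymmetry is the ratio of corrected densities, numerator chosen as
the pole containing the overly long centriole(s) or, in control mode, the
pole with the higher centrin density (ratio ≥ 1 by construction).
Microtubule-regrowth quantification subtracts the mean of the
minimum-intensity z-projection from every plane (clamped at 0),
sum-projects, and integrates over a 2.2 µm disk at each pole. ROIs are
auto-seeded at the two brightest centrin foci (separation floor 5 µm so
both poles, not two centrioles of one pole, are picked) and then
re-centred on the local tubulin centre of mass — the automated analogue of
a human placing the ROI on the aster. Centrin–PCM association uses
Spearman rank correlation (mid-rank ties, two-tailed p).

## Synthetic data

The generator emulates the acquisition the pipeline targets: 86.7 nm
lateral pixels, 200 nm plane spacing, 50 planes (10 µm, within the
10–14 µm band), EMCCD-like Poisson photon noise plus Gaussian read noise
(sd 2) over a 5-photon background. A default field (512 px ≈ 44 µm) holds
one rounded mitotic cell — a 10 µm-radius chromatin plate, a 12.5 µm
cytoplasm, spindle fibres and asters between poles 15 µm apart — among
eight dimmer interphase nuclei. Per-cell test fields use the same cell in
a 352 px field with two interphase neighbours.

Centrioles are line ("capsule") kernels of the specified length and 3D
orientation (tilt ≤ 30° out of the imaging plane), with constant photon
density per nm (25 photons/nm), convolved with an anisotropic Gaussian PSF
(σxy 100 nm, σz 300 nm); total centrin signal per centriole is therefore
proportional to its length. CP110 renders the same geometry at 20
photons/nm for non-decoy centrioles. Satellite decoys are centrin-only
clusters (400 nm, 22 photons/nm) placed 1.5–3 µm from a pole — bright
enough to pass the candidate area filter, which is precisely the
single-marker false-positive behaviour they exist to reproduce.

Placement: centrioles scatter in a pole-centred ball of radius
1.2 µm·(n_pole/2)^⅓ (constant packing density as rosettes grow), with a
minimum capsule-to-capsule gap of 3 px (260 nm) and a *resolvable
configuration* floor for pole-mates: lateral separation ≥ 420 nm or axial
separation ≥ 650 nm. The floor reflects the acquisition physics — two
centrioles closer than the PSF in every direction produce one
diffraction-limited spot that no intensity-based method can count as two —
and the original screening workflow, where counting was performed on
deconvolved data and human-curated. Without it, exact-count accuracy is
capped near 0.8 by unresolvable merges regardless of algorithm.

Amplified cells draw counts from a 5–12 distribution peaked at 5–8;
normal lengths are N(425, 40) nm clipped to [250, 500]; overly long
lengths are lognormal (median 800 nm) clipped to [550, 2500]. The
fast path `simulate_population` samples per-cell counts and lengths
without rendering, optionally coupling over-elongation to amplification
through an odds ratio on the per-centriole rate.

Presets: `SimulationProfile.dim()` produces a low-contrast wide field
(bright haze, dim sparse interphase, big textured chromatin) whose Otsu
S/N falls below 2.5, exercising the robust-threshold branch;
`SimulationProfile.regrowth(pole_ratio)` emulates a cold-treated
regrowth assay (no cytoplasmic microtubules, compact asters, optional
pole asymmetry).

### What the generator does not emulate

Real image features outside the model: optical aberrations and depth-dependent
PSF changes, uneven illumination, camera fixed-pattern noise, autofluorescence,
touching/overlapping mitotic cells, mitotic phases (the chromatin is always a
rosette/plate), deconvolution artefacts, and biological variation in marker
stoichiometry. Passing tests therefore demonstrate the algorithmic chain is
correct under the stated imaging model, not that the thresholds transfer
unchanged to any particular microscope; the original workflow interposed
deconvolution and two manual-curation passes, both of which this package
supports but the tests do not require.

## Known limitations

- **250 nm centrioles** are at the detection floor under the raw
  (undeconvolved) PSF: their above-threshold footprint straddles the
  0.1 µm² candidate minimum, so detection is unreliable (~25–50% in the
  test conditions) and measured lengths are PSF-bounded. The 500–2000 nm
  range is recovered with median absolute relative error well under 15%.
- Side-by-side parallel centrioles closer than ~400 nm laterally merge
  irrecoverably (the splitting plane is always normal to the long axis).
- The local background term of the integrated density assumes the object
  spans a small fraction of the z-range; thick objects contaminate their
  own background estimate.
- The min-projection background estimator of the regrowth assay
  under-subtracts Poisson-distributed backgrounds (the minimum of n draws
  sits ~2σ below the mean); the assay is designed around low diffuse
  background, as after cold treatment.

## Problem sizes used by the test-suite and acceptance script

Rendered-field studies use the 352 px per-cell field: 50 cells (counts
2–8) for count recovery and voxel conservation, 5 cells per target length
for length recovery, 12 fields for mitotic recall, 3 fields per condition
for satellite discrimination and pole asymmetry, and one dim-preset field
for the robust branch. Statistical power uses 100 replicates of ~5000
centrioles sampled without rendering; the type-I rate uses 1000
replicates so the binomial noise of the estimate (sd ~0.7 points) sits
well inside the ±2-point calibration band. At these sizes the
rendered-field estimates (count accuracy, pooled length error, pole
ratios) move by a few points between seeds; `scripts/acceptance.py`
reports the problem size next to every value so that spread can be
judged. These sizes were
chosen so the full suite exercises every stage end to end on a single CPU
while keeping the binomial error of each estimate well inside the margins
being asserted.
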