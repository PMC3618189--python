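# Methods

This note documents the measurement model, the synthetic-data generator, the
numerical conventions and the open design choices behind `trabmri`. Units:
lengths in mm, areas in mm², BV/TV in percent, Tb.N per mm, densities per
mm²; the default voxel geometry is 0.195 × 0.195 × 1.0 mm, emulating a 1 T
peripheral gradient-echo acquisition of the distal radius (bone dark, marrow
bright).

## Per-slice measurement model

All structural metrics are **two-dimensional, per-slice, then averaged**
over the 8-slice analysis volume. The acquisition voxels are ~5× anisotropic
(195 µm in-plane vs 1 mm through-plane); running 3-D structural operators
across 1 mm slices would be dominated by slice thickness, so the classical
"maximal spheres" of the model-independent distance-transform method become
maximal inscribed **discs** in-plane, and skeletonization/network analysis
is 2-D. This is the central modeling commitment of the package and the main
caveat when comparing its absolute values to 3-D implementations.

### Endosteal segmentation

The cortical shell is far thicker than any trabecula, so a morphological
opening with a disc of half the guaranteed rim thickness (default
`min_rim_thickness_mm = 0.8`) erases the trabecular network and keeps the
shell; the region it encloses is the region of interest. Trabeculae attach
to the rim and leave small intrusions in the enclosed region; since the
endosteal border of the radius is near-convex, the convex hull of the
enclosed region (clipped to the inside of the shell) restores the border.
On synthetic discs of radius 9.2 mm the recovered area is within ~1 % of
π·9.2² ≈ 266 mm². A slice with no closed rim raises an error and is flagged
for a manual mask rather than guessed.

### Binarization

Otsu's threshold on the in-mask histogram, per slice, recorded on the
output for audit. Intensities are oriented so bone is the low class before
thresholding, which makes the result exactly symmetric under contrast
inversion (`bone_is_dark=False`). A constant in-mask histogram is an error,
never an arbitrary split.

### Holes (region growing)

Marrow components are grown by breadth-first flood fill from raster-order
seeds with **4-connectivity for marrow and 8-connectivity for bone** — the
standard dual pair that prevents both phases from crossing at a pixel
corner. Hole count = number of regions grown; hole size = mean region area
× voxel². Components touching the endosteal border are counted as holes by
default (they are intertrabecular space, and observed in-vivo counts of
~70 per slice suggest no aggressive exclusion); `include_boundary=False`
moves them to an explicitly reported excluded class. No minimum hole area is
imposed. With boundary components included, hole area + bone area = mask
area exactly. When a slice has no holes the mean is reported as undefined
(`None`), never 0/0.

### Tb.Th / Tb.Sp (maximal inscribed discs)

For a phase pixel centre *c*, let d(*c*) be the Euclidean distance to the
nearest opposite-phase pixel centre inside the region of interest; pixels
outside the region neither block nor carry discs. The maximal disc at *c*
has radius d(*c*) − ½ (the phase boundary lies halfway between pixel
centres), and the local thickness at pixel *p* is the diameter of the
largest maximal disc covering *p*. Tb.Th is the mean over bone pixels
(obstacles = marrow), Tb.Sp the mean over marrow pixels (obstacles = bone),
scaled by the in-plane voxel size. With this convention a straight strut
*w* pixels wide measures exactly *w* pixels; bands touching the image edge
behave as half-open slabs (no obstacle on the open side), which is why test
fixtures evaluate interior bands. The implementation (distance transform +
radius-grouped dilation) is verified against an exhaustive all-centres ×
all-radii search on instances up to 64×64. Note that Tb.Sp and hole size
describe the same anatomy through different operators (disc diameters vs
region areas) and are deliberately computed independently.

### Tb.N

Tb.N = (BV/TV)/Tb.Th by the standard histomorphometric plate-model formula,
recomputed **from the slice-averaged BV/TV and Tb.Th** so the identity holds
exactly on every reported profile (whether the original software derived it
per-slice or from averages is unknowable; averages are consistent with the
internal ratios of published summary tables).

### Skeleton network

Any topology-preserving 2-D thinning is acceptable (the package uses the
standard scikit-image skeletonization); correctness is asserted
topologically — the skeleton has the same Euler number (components minus
holes) as the input — not geometrically. Skeleton pixels with ≥3 8-connected
skeleton neighbours are junction pixels; **8-adjacent junction pixels are
merged into a single node** before counting (per-pixel counting is a known
inflation pitfall). A branch is one 8-connected component of the skeleton
minus junction pixels, plus one zero-length branch per directly touching
pair of distinct node clusters; an isolated fragment or pure loop counts as
one branch. Densities divide the merged node count and branch count by the
endosteal area.

## Longitudinal analysis

Changes are computed between the two slice-averaged per-visit profiles
(not per-slice changes averaged afterwards — the order matters for ratio
variables): absolute = follow-up − baseline, percent = 100 × absolute /
baseline, with zero-baseline variables flagged undefined rather than
dropped. Precision over replicates: RMSCV% = 100·√(mean over subjects of
(SD/mean)²) and ICC(1,1) from the one-way random-effects decomposition
(single measurement). The replicate structure (re-scan vs re-analysis) is
the caller's choice; reported figures are only comparable across identical
replicate designs.

## Registration

Through-plane matching is restricted to **integer slice offsets** (slice
thickness ≫ in-plane resolution; interpolating across 1 mm slices would
fabricate data), searched exhaustively within ±3 slices and scored by the
mean normalized cross-correlation of overlapping slice pairs after in-plane
alignment — NCC is invariant to the global intensity rescaling expected
between visits. The in-plane transform is rigid only (the forearm is braced;
affine terms are unjustified): translation by phase correlation (10×
subpixel refinement), rotation by a small discrete search (±3° by default),
estimated per slice pair with the pair-level transform taken as the
per-slice median. Pairs whose best score falls below `min_match_score`
(default 0.5) raise a registration error; the pipeline excludes such
subjects with a logged reason, the analogue of motion-artifact exclusions.
The distal reference slice can be supplied manually (mirroring
operator-driven practice) or detected automatically on synthetic stacks
from the per-slice bone-fraction drop at the dense metaphyseal band.

## Synthetic-data generator

**Texture.** Trabecular texture is a thresholded smoothed Gaussian random
field (chosen over Voronoi-edge lattices for its single smoothness
parameter and natural hole-size dispersion): white noise is smoothed at a
correlation length calibrated per slice by bisection so that the number of
4-connected marrow components inside the endosteal disc hits
`hole_count_target`; the threshold is the field quantile realizing
`target_bvtv` (exact to quantile granularity). An unreachable target raises
`InfeasibleParameters` — never silent clipping. With the default targets
(BV/TV 0.477, 70 holes, radius 9.2 mm) the mean hole area lands at
≈ 2.0 mm² and the endosteal area at ≈ 266 mm², the scales reported for the
distal radius in vivo. `target_tbth` documents the intended strut scale;
the realized Tb.Th is emergent (≈ 0.45–0.55 mm at defaults).

**Intensity.** Two-class rendering (bone 60, marrow 190, background 170
grey-level units), Gaussian PSF of FWHM `psf_fwhm`, additive Gaussian noise
`noise_sd`. The source study reports no grey-level statistics, so contrast
and noise are free parameters; the defaults (FWHM 0.2 mm, noise SD 15 ≈
12 % of the class separation) are chosen to make binarization genuinely
non-trivial while keeping the measurement chain able to track ground truth
(pixelwise agreement ≈ 99.5 %, measured BV/TV within ~0.5 points). Slices
are independent 2-D textures; through-plane blur is deliberately absent
because every measurement is per-slice.

**Follow-up.** Derived from baseline ground truth: the stated fraction of
trabecular-bone pixels is removed surface-first (distance-to-marrow
ordering with seeded tie-breaks — resorption-like thinning; the realized
pixel count is exact to rounding), then a rigid in-plane transform
(nearest-neighbour, so ground truth stays binary) and a cyclic integer
slice offset are applied and grey levels re-rendered with fresh noise. A
transform that clips the cross-section against the field of view is an
error. All perturbation parameters are recorded.

**Cohorts are simulated on two levels.** The outcome table draws
per-subject baseline values and percent changes at the scales of the
emulated study (baseline means/SDs and percent-change SDs reconstructed
from its published summary tables), with the planted group effect
`effect_pct_change` added to the diabetes group and an ethnicity offset on
the primary outcome, centred on the expected Caucasian fraction so that it
induces the covariate–outcome correlation (default sized to give r ≈ −0.36
at the default group sizes of 14 vs 21 and Caucasian fractions 0.8/1.0)
without shifting group means. Image stacks can additionally be rendered per
subject-visit, driven by the table's BV/TV, hole-count and endosteal-area
targets, with structural change rendered as bone loss plus rigid
misalignment (the rendered hole-count target is capped at the feasible
density for the drawn disc size). A pixel-level generator cannot realize
nine correlated outcome changes simultaneously, so **parameter-recovery and
error-rate claims about the statistics are established on the numeric
table, and pipeline claims (registration, segmentation, measurement
fidelity) on rendered stacks** — passing tests therefore demonstrate the
measurement chain on this texture family and the inferential machinery on
the emulated statistical structure, not the biological realism of either.
Known realism gaps: the random-field texture is more reticulated than real
trabecular bone (skeleton branch/nodal densities run ~2–3× the in-vivo
values, with the correct ordering and area-normalization); baseline Tb.N is
drawn consistent with BV/TV/Tb.Th but its percent change is an independent
draw; no motion artifact beyond rigid misalignment; no dropout simulation.

## Inference

`percent_change ~ group + covariates` by OLS per variable. Reported group
means are least-squares means — predictions at the grand covariate mean —
with SEs from the coefficient covariance; the group p-value is the OLS
t-test on the group coefficient, which with no covariates reduces exactly
(to 1e-10 in tests) to the pooled-variance two-sample t-test. Zero-variance
covariates are dropped with a warning (the degenerate all-one-ethnicity
cohort case); collinear designs fail naming the offending columns; ≥
(covariates + 2) subjects per group are required. Covariate screening is a
Pearson correlation with inclusion at p < 0.05. Descriptive comparisons use
the pooled-variance t-test by default (Welch optional) and chi-square
without continuity correction (optional). Holm's step-down correction uses
**m = 9** — all nine variables including the primary — because that family
size exactly reproduces the published worked example (0.010×9 = 0.090,
0.119×8 = 0.952, remainder capped at 1.00); under global-null simulation
the nine-variable battery's family-wise error is ≤ 5 % within Monte-Carlo
error (1000 replicates). Ordinary (unweighted, non-robust) least squares is
assumed throughout.

## Problem sizes and determinism

Default synthetic scenes are 128×128 pixels (25 mm field of view), 10–20
slices per stack; test and acceptance runs use 8-slice volumes, a few
stacks for image-level checks, 200 replicates for effect recovery and
500–1000 for error-rate estimates — sizes at which every statistical
tolerance stated in the tests is comfortably resolved. All randomness flows
from explicit integer seeds through numpy Generators (per-slice and
per-subject streams are derived from the parent seed), so fixed seeds give
bit-identical stacks, tables and pipeline outputs; the pipeline writes a
manifest (config hash, seed, version) and reruns reproduce artifacts
byte-for-byte.

## Limitations

- 2-D per-slice morphometry: absolute Tb.Th/Tb.Sp are not interchangeable
  with 3-D sphere-based values at isotropic resolution.
- The registration similarity metric, search ranges and the single-metric
  matching rule are documented stand-ins for an unspecified original
  protocol.
- Whether hole statistics were originally pooled across slices before or
  after averaging is unknown; this package computes per-slice values and
  averages them.
- Synthetic precision (RMSCV/ICC) reflects the noise model only and is not
  comparable to in-vivo re-scan precision.
- No cortical-bone analysis, no 3-D connectivity indices, no plate/rod
  (SMI) indices, no mixed-effects longitudinal modeling.
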