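# Methods

This note documents the synthetic image model, the numerical choices made
in each analysis stage, and the rationale behind every default. Units are
micrometres (µm) unless stated otherwise; voxel arrays are ordered
(z, y, x).

## 1. Synthetic spheroid generator

Real spheroid confocal data cannot be redistributed, so every analysis
stage is validated against a generator whose ground truth is known
exactly: the occupancy mask, every nucleus centroid, every marker label,
the actin mode and the shape class.

### Geometry

Three shape families, voxelised on an auto-sized grid with a margin of 5
voxels per side (a fixed `grid_shape` may be supplied instead; a grid too
small for the shape is rejected with the offending axis named):

| family | parameters | default | true class |
|---|---|---|---|
| `sphere` | `radius_um` | 50 | spherical |
| `ellipsoid` | `semi_axes_um` (z, y, x) | (40, 40, 80) | elongated if max/min axis ≥ 2, else spherical |
| `budded` | `main_radius_um`, `bud_radius_um`, `bud_offset_um` (bud centre displaced along +x) | 45, 20, 45 | budded only if the bud is resolvable: offset > main − bud (it protrudes) and bud ≥ 0.25 × main; otherwise spherical |

### Nuclei

`n_nuclei` (default 600) centres are drawn by rejection sampling inside
the mask with a hard minimum pairwise spacing (default 7 µm for 8 µm
nuclei, i.e. a dense epithelium with slight rendering overlap). Sampling
stops with a warning if the attempt budget `max(1000, 200 n)` is
exhausted — the spacing constraint, not the request, then determines the
count. Each nucleus is rendered as an anisotropy-aware Gaussian blob with
σ = `nucleus_radius_um` / 2 (so the ±2σ support matches the nominal
diameter), splatted only within its ±3σ window.

### Channels

- **Nuclear (`dapi`)** — nucleus blobs at `nuclear_amplitude` (100) plus
  a diffuse haze at `scatter_fraction` (8 %) of that amplitude over the
  whole occupancy. The haze models out-of-focus and scattered light in
  dense tissue; it matters because a blob-only nuclear channel has *no*
  continuous foreground between nuclei, which no global threshold could
  segment into one solid aggregate — real dense spheroids do produce
  continuous signal.
- **Markers** (one channel per `MarkerModel`) — every nucleus is rendered
  at `marker_baseline` (20); positive nuclei at baseline ×
  `positive_gain` (5). Labels are Bernoulli draws with
  `p_positive_inside` / `p_positive_outside`; in `distal_cap` mode the
  "inside" region is the distal `cap_fraction` of the extent along the
  shape's principal axis, which models apically/distally confined
  expression domains.
- **F-actin (`factin`)** — `cortical`: a band within `actin_shell_um`
  (5 µm) of the surface (by Euclidean distance transform) at
  `actin_amplitude`, with the interior at 20 % of it; `central`: a
  Gaussian focus (σ = 0.35 × equivalent radius) at the centroid;
  `uniform`: constant inside the mask.

### Optics and noise

All channels are blurred with an anisotropic Gaussian PSF
(`psf_sigma_um` = (1.5, 0.6, 0.6) — a typical 40× confocal axial/lateral
resolution ratio), then corrupted with Poisson shot noise
(`noise_poisson_scale` = 1.0; 0 disables) and additive Gaussian read
noise (sd 3), clipped at 0, stored as float32. Default voxel spacing is
(2.0, 0.5, 0.5) µm — 0.5 µm lateral sampling with 2 µm optical sections.

Not emulated: uneven illumination and vignetting, depth-dependent
attenuation and spherical aberration, chromatic shifts between channels,
autofluorescence gradients, debris and neighbouring aggregates, detector
offset/gain structure. Tests therefore exercise the estimators'
correctness and noise robustness, not acquisition-artefact correction.

Everything derives from a single `rng_seed`, and identical specs render
bit-identical stacks.

## 2. Segmentation

The 2D route mirrors a common interactive protocol: maximum-intensity
projection of the nuclear channel → Gaussian pre-filter (σ = 3 px) →
2-class k-means on the 256-bin intensity histogram (threshold placed
midway between the class means; equivalent to minimising within-class
variance, verified in the tests against an exhaustive search) → minimum
object size 10,000 px → hole filling → largest component. A constant
image warns and yields an empty mask; an empty final mask raises
`SpheroidNotFoundError`.

The 3D route pre-filters at a *physical* σ of 4 µm (so anisotropic
stacks are smoothed isotropically in real space), thresholds the whole
volume, and scales the minimum size to `10,000 × z_extent / 4` voxels,
where z_extent is the slice span of the largest candidate component. The
divisor reflects that a convex body fills only part of its bounding
cylinder, and that the 10,000 px 2D floor is itself of the same order as
a 100 µm spheroid's projected area at 0.5 µm pixels — scaling by the
full z-extent would exceed the spheroid's own voxel count. The value is
configurable (`min_object_size_3d`).

## 3. Morphometry

- **Volume**: voxel count × voxel volume (exact for the discrete mask).
- **Surface area**: marching-cubes isosurface (level 0.5) of the padded
  occupancy after light Gaussian smoothing with σ = 0.7 × max(spacing).
  Smoothing suppresses the staircase over-estimation of smooth surfaces
  (a digital sphere meshes to ψ ≈ 0.99–1.00 instead of ≈ 0.92 unsmoothed)
  at the cost of rounding sharp corners: a 30-voxel cube's area is
  underestimated by ≈ 4 % (bias decays as σ/side, ≈ 1 % at side 120).
  Spheroids are smooth, so the default favours them; σ is configurable.
  Mesh-based area is used instead of exposed-voxel-face counting, which
  overestimates by up to 50 % and would systematically depress ψ.
- **Sphericity**: Wadell's ψ = π^(1/3)(6V)^(2/3)/A, computed from the
  two estimates above. Validated against closed forms: analytic sphere
  ψ = 1 exactly, cube ψ = π^(1/3)·6^(2/3)/6 ≈ 0.806, prolate spheroid
  a:b:b with eccentricity e: A = 2πb²(1 + (a/(be))·arcsin e)
  (3:1:1 → ψ ≈ 0.846); the voxel pipeline reproduces the prolate family
  1:1:1 → 5:1:1 within 3 % and decreases monotonically along it.
- **Principal axes**: eigenvalues λ of the covariance of foreground
  voxel coordinates (physical units); semi-axes = √(5λ), exact for a
  solid ellipsoid. Planar/linear masks raise a degeneracy error.
- **Protrusions**: morphological opening implemented with distance
  transforms (erode at radius r, dilate back), honouring anisotropic
  spacing. Default opening radius 0.5 × equivalent radius: an opening
  can never remove a bud locally thicker than its structuring ball, so a
  small-radius opening would keep every plausible bud attached and the
  detector would always report zero. A residue component counts as a
  protrusion only if it holds ≥ 1 % of the mask volume *and* protrudes
  ≥ 0.25 × r_eq beyond the opened body — the depth test rejects the
  thin surface shell that an opening shaves off a noisily segmented but
  genuinely round mask (measured depth ≤ 0.15 r_eq, versus ≥ 0.4 r_eq
  for true buds).
- **Classification**: *deformed* = ψ < 0.7 (the printed deformation
  threshold) **or** ≥ 1 protrusion **or** elongation ratio a/c ≥ 2.
  Deformed shapes with a/c ≥ 2 are `elongated`, other deformed shapes
  `budded`, the rest `spherical`. Elongation must be its own trigger: a
  smooth 2–3:1 prolate keeps ψ ≈ 0.85–0.92 > 0.7, so a ψ-only rule would
  call clearly elongated bodies spherical. Both thresholds are
  configurable and recorded in provenance.

## 4. Nuclei and markers

LoG detection with σ = r/√3 per axis in voxel units (the scale that
maximises the LoG response of a ball of radius r), local maxima above
10 % of the global peak inside the mask, then a deterministic greedy
merge of peaks closer than 0.8 × the expected diameter (strongest first,
ties by coordinate). Per-nucleus means are sampled in an anisotropy-aware
ball (default radius 4 µm) clipped at image borders.

Positive calls: Otsu's threshold on the distribution of per-nucleus
means (default), or a manual absolute threshold. Otsu is
scale-invariant, which is desirable for staining-intensity robustness
but makes it *provably unable* to distinguish an all-negative from an
all-positive population (they differ only by scale) — for panels that
include 0 % or 100 % true fractions, calibrate a manual threshold on
control samples (the benchmark suites use the midpoint of the median
per-nucleus means of an all-negative and an all-positive control, the
in-silico analogue of gating on stained/unstained controls).

Readouts: percent-positive per channel (of all detected nuclei),
double-positive percentage for channel pairs (logical AND of calls), and
a polarisation index — the fraction of positive nuclei in the distal
half of the projection onto a given axis (halves split at the midpoint
of the all-nuclei extent). With `orient="auto"` the index folds to
[0.5, 1] (0.5 = unpolarised); `orient="positive"` keeps the direction of
the supplied axis.

## 5. F-actin ring decomposition

The whole-spheroid mask comes from the 2D nuclear-channel segmentation
(the actin channel is never used for masking, avoiding circularity). The
inner core is the mask scaled towards its binary centroid by factor 0.75
per axis — "reduced by 25 %" is read as 75 % remaining per linear axis,
so a disk's inner core holds 0.75² = 56.25 % of the area — intersected
with the whole mask so the partition inner ∪ outer = whole,
inner ∩ outer = ∅ holds for any shape (scaling uses nearest-neighbour
resampling of the inverse affine map plus hole filling). The readout is
mean F-actin MIP intensity in the outer ring divided by the inner core
(`ratio_periphery_to_centre`): > 1 indicates cortical actin, < 1 central
accumulation, 1.0 exactly for uniform intensity. The ratio is reported
as missing when the core mean is zero.

## 6. Pipeline determinism

Simulated batch items without an explicit seed get `config.seed + index`.
The config hash (sha256 over the canonical YAML, truncated to 16 hex
chars) excludes the output directory and log verbosity, so relocating a
run does not change its recorded identity. CSV floats are written with
`%.6g`; identical config + seed is byte-identical. Failures are isolated
per input: a corrupt stack produces a `failed: …` row and a non-zero CLI
exit code, never an aborted batch.

## 7. Benchmark problem sizes

The suites in `spheromet.validation` (shared by the acceptance tests and
`scripts/acceptance.py`) use: 100 µm spheres at default noise for Dice;
a 256² disk of radius 100 px for ring geometry; 20 simulations (10
cortical, 10 central) for ratio-direction recovery; 20 spheroids × 500
nuclei spanning true fractions {0, 25, 50, 75, 100} % for marker
recovery; 10,000 label draws for coexpression; and 30 spheroids (10 per
family, with randomised geometry) for classification. One full pass
takes ≈ 4 minutes on one CPU.
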