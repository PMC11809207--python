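# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `mitomorph`.  Everything stated as a measured number here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Coordinate and unit conventions

Voxel grids are indexed 0-based in (z, y, x) order; voxel centres sit at
`index × spacing`; all lengths are µm, areas µm², volumes µm³.  Every image
operation appends a provenance record (operation name + parameters), so a
processed stack carries its own history and the stage order is assertable.

## Synthetic ground truth

The generator is the package's answer key: the study's raw live-imaging
stacks are not redistributable, so validation runs against synthetic data
whose truth is exact by construction.

**Networks.**  Branches are straight segments grown from existing nodes
(rejection-sampled for a minimum surface-to-surface clearance, default
0.2 µm), each with a constant radius.  Straight centrelines keep every true
branch length exactly computable, and constant radii make the "true
diameter" unambiguous for thickness-recovery tests.  `attach_probability`
interpolates between a connected network (1) and fully disjoint tubes (0).
Rasterization marks voxels whose centres lie within the branch radius of the
centreline; a single branch therefore rasterizes to a capsule (cylinder +
hemispherical caps), and the recorded true network volume is the foreground
voxel count × voxel volume.

**Imaging model.**  `image = Poisson(photon_scale · PSF⊛mask + background)
+ N(0, read_noise²)`, clamped non-negative — the standard fluorescence
noise model, with both noise components switchable to zero.  Defaults:

| parameter | default | rationale |
|---|---|---|
| psf_sigma (z, y, x) | (0.15, 0.06, 0.06) µm | Airyscan-class resolution (FWHM ≈ 0.35 µm axial / 0.14 µm lateral), matching the detector used for live TMRM imaging of this preparation |
| photon_scale | 50 photons | moderate-SNR live imaging of a potentiometric dye at low laser power; no published photon statistics exist for these images, so this is a chosen, not fitted, value |
| read_noise_sigma | 1.0 | small relative to shot noise, as for modern GaAsP/Airyscan detectors |
| background | 5 + 0.1/µm lateral gradient | residual cytoplasmic dye + illumination falloff |

Anisotropic acquisition is emulated at 0.18 µm lateral / 0.9 µm axial where
the resampling stage is exercised; the synthetic benchmarks otherwise
generate directly at 0.1 µm isotropic, the regime the real analysis
resamples into.

**Phantoms and mosaics.**  Spheres/ellipsoids/stacked profiles carry
closed-form volumes and analytic per-slice section areas (the stand-in for
manual per-slice annotation).  Apical mosaics place regular polygons in
disjoint grid slots (areas drawn from a lognormal law, mean 25 µm² — the
scale of embryonic hair-cell apical surfaces), so polygons can never overlap
and each true area follows exactly from its vertices.

## Preprocessing

Stages run in a fixed order: isotropic resampling (linear interpolation,
target = smallest input spacing), slice-wise rolling-ball background
subtraction (radius 50 px), unsharp masking, non-local-means denoising, and
difference-of-Gaussians band-pass (σ 2–4 px) clamped non-negative.
Choices the protocol leaves open:

- Rolling ball is applied per 2D slice (the common interpretation of the
  cited operation, which specifies a single pixel radius, not a 3D ball).
  For radii above 16 px the background is estimated on a proportionally
  downscaled slice and rescaled — the same shrink trick the original
  implementation uses — keeping the 50 px default tractable.
- Unsharp masking uses `(I − w·G_r(I)) / (1 − w)` with defaults r = 3 px,
  w = 0.6; non-local means defaults to patch 5, search 11, strength 2× the
  noise σ estimated from the stack.  None of these constants are given by
  the protocol; all are exposed in `PreprocessConfig` and recorded in
  provenance.
- All convolutions use reflective/nearest padding to avoid edge dimming in
  thin stacks; every stage clamps at zero, so non-negativity holds end to
  end, and every stage is deterministic.

## Segmentation

The trainable-segmentation stage mirrors the interactive workflow: sparse
labels from a single annotated slice train a classifier that segments the
rest of the stack.  The classifier is a random forest (50 trees, fixed
seed) over a per-voxel feature stack — raw intensity plus, at each scale
(default 1 and 2 px), Gaussian blur, gradient magnitude, Laplacian and the
extreme Hessian eigenvalues (1 + 5·|scales| channels, computed in 3D on the
isotropic grid).  The original tool names no model, so the classifier sits
behind an interface with a plain intensity-threshold fallback.  Class
imbalance is handled by uniform subsampling of the majority class.
Binarization thresholds the foreground probability at 0.5; optional removal
of components < 5 voxels (26-connectivity) is off by default because the
protocol mentions no cleanup.

## Skeleton morphometry

Masks are thinned by 3D medial-axis (Lee-style) thinning, which preserves
topology — connected components map one-to-one onto skeleton components.
The branch graph uses 26-connectivity throughout: end points have one
skeleton neighbour, junctions three or more; adjacent junction voxels (a
thinning artefact) merge into one node; pure cycles get an anchor node;
isolated voxels are degenerate zero-length branches.  Terminal spurs
shorter than 0.3 µm (roughly one tube radius) are pruned by default —
thinning of thick tubes grows such twigs at junctions and surface bumps,
and they otherwise fragment the branch decomposition.

Local thickness is the diameter of the largest sphere containing the voxel
that fits inside the mask, computed by sphere-painting from the Euclidean
distance transform in decreasing-radius order.  Per-branch thickness is the
mean of this map along the branch path (the aggregation is not specified by
the source protocol; the mean is used for all per-branch summaries).

Descriptor decisions where the protocol is ambiguous:

- **"Euclidean distance"** is implemented as the mean straight-line
  endpoint separation per branch (the cited skeleton-analysis tool's
  output); the dimensionless tortuosity ratio path/Euclidean is also
  computed and stored (`mean_tortuosity`) but excluded from the
  8-descriptor vector.
- **"Branch aspect ratio"** is path length / mean branch thickness; the
  quantity is not defined in the source protocol, and this choice is
  recorded in output metadata.
- The source text says "seven measurements" but lists eight; eight are
  implemented.
- The longest shortest path is the graph diameter over end/junction nodes,
  weighted by branch path lengths, maximized over connected components;
  an empty graph yields 0 with a warning.

## Cell-scale metrics

The Cavalieri estimator is implemented in physical units: volume =
Σ sampled areas × sampling interval, with the protocol's "×5" exposed as
the derived multiplier sampling_interval / optical_section
(0.9 µm / 0.18 µm = 5).  It is exact for prisms and recovers a 4 µm sphere
phantom to well under 10% under the default protocol.  The "top 65% of the
fluorescence histogram" is interpreted as the cumulative-count quantile
(retain the brightest 65% of pixels), not 65% of the intensity range — the
count quantile is scale-invariant; the interpretation is configurable.  A
constant image makes the quantile degenerate and retains everything, with a
warning.  Polygon areas use the shoelace formula; cells are counted when
their centroid falls inside the 50 µm × 50 µm ROI (centred on the field; no
edge rule is stated by the protocol).  Nuclear area is the same polygon
operation with a different structure tag.

## Statistics

PCA standardizes (z-scores) the descriptor columns by default — the
convention of standard morphometric PCA workflows; the flag is stored in
the model so either variant is reproducible.  Components come from the SVD
of the standardized matrix; signs are fixed by forcing each component's
largest-magnitude loading positive, making scores comparable across runs
and projections deterministic.  Confidence ellipses come in two flavours:
the normal-population coverage ellipse (default, matching the usual PCA
visualisation; radii scaled by √χ²₂(q)) and the Hotelling mean-confidence
region.  Group comparisons: two-way ANOVA with Type II sums of squares (the
designs are near-balanced, and the convention must be explicit), unpaired
two-tailed t, and Kruskal–Wallis with pairwise Mann–Whitney post-hocs; all
contrasts are Sidak-adjusted, p' = 1 − (1 − p)^m.

## Benchmark design and problem sizes

Benchmarks run the full path — render → preprocess → segment → skeletonize
→ measure → PCA — on 48³–64³ voxel cells at 0.1 µm isotropic spacing;
dozens of such cells run in a few minutes on one CPU while leaving branch
lengths several-fold larger than the PSF.

- **Parameter recovery** uses 21 cells of 3 disjoint tubes each (radii
  cycling 0.2/0.3/0.5 µm, constant per cell).  Disjoint tubes are the
  deliberate choice: the per-branch truth comparison is only well defined
  when every truth branch is individually resolvable — in dense networks
  adjacent mitochondria cannot be separated, which is a documented limit of
  the real measurement too.
- **Regime separation** generates "fused" (fewer/longer/thicker) vs
  "fragmented" (more/shorter/thinner) cells, 15 per regime, with an effect
  parameter interpolating to identical conditions at 0; separation is
  scored as 95%-ellipse overlap (intersection / smaller-ellipse area) in
  PC1–PC2.
- **Segmentation quality** trains on 200 labels per class from the densest
  single slice of one default-SNR stack and scores whole-stack Dice.

## What the synthetic benchmarks do and do not show

The generator reproduces the pieces of real data that the measurements are
sensitive to — tubular geometry, PSF anisotropy, shot noise, background
gradients — but not organelle crowding at E14-proximal densities, motion,
photobleaching, cytoplasmic autofluorescence structure, or real annotation
variability (labels come from the truth mask, an upper bound on annotation
quality).  Passing benchmarks therefore demonstrates that the measurement
chain is unbiased and self-consistent on resolvable structures; it does not
certify accuracy on arbitrarily dense networks, where only relative
comparisons are meaningful.

## Numerical notes and degenerate inputs

Rasterized volumes converge to the analytic capsule volume as spacing → 0;
radii commensurate with the grid (r an exact multiple of the spacing) put
lattice points exactly on the boundary and perturb the voxel count, so
convergence tests use incommensurate radii.  Skeletonization and thickness
require isotropic voxels and raise a contract error directing to the
resampling stage otherwise.  Empty masks yield empty skeletons; empty
graphs yield an all-zero descriptor record flagged degenerate and are
excluded from the PCA (logged per cell).  Groups with fewer than three
cells skip their ellipse with a warning.  Per-cell failures in a pipeline
run are isolated and logged with cell id and stage; they never abort the
run.
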